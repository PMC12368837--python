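# Methods

This note records the models behind `lareims`, their assumptions, the
defaults that matter, and what the synthetic benchmarks do and do not show.

## 1. The interface model

### Free jet

Gas expands from stagnation conditions (`P0 = 101325 Pa`, `T0 = 300 K`,
nitrogen: molar mass 0.028 kg/mol, γ = 1.4, μ = 1.8·10⁻⁵ Pa·s, molecular
diameter 3.7 Å) through a capillary of bore `d = 0.6 mm` into a first vacuum
stage at `P1 = 600 Pa`.  These are **calibrated defaults, not measured
instrument values**; they are chosen so that the Mach disk of the resulting
underexpanded jet falls near 5 mm, the regime the package is meant to
explore.  The model is deliberately analytic rather than a kinetic gas
solution:

* **Mach disk**: the standard empirical correlation
  `x_M = 0.67 d √(P0/P1)` (5.22 mm at the defaults).
* **Centerline Mach number**: Ashkenas–Sherman far-field correlation
  `M(z) = 3.65 ((z − 0.4 d)/d)^0.4` for γ = 1.4, blended linearly to the
  stagnation limit `M → 0` at the exit plane over the first capillary
  diameter.  Temperature, pressure and density follow the isentropic
  relations; the adiabatic identity `T (1 + (γ−1)/2 M²) = T0` holds at
  every evaluated point by construction.
* **Downstream of the Mach disk** the gas is a uniform subsonic drift at
  the post-normal-shock Rankine–Hugoniot state computed from the pre-shock
  centerline Mach number (at the defaults: M ≈ 0.39, T ≈ 291 K,
  p ≈ 580 Pa, u ≈ 136 m/s).  No shock structure beyond this single normal
  shock is modeled.
* **Off axis**, velocity decays on a Gaussian similarity profile whose
  half-width grows as `w(z) = d/2 + 0.2 z`; a small outward radial
  component (`u_r = u_z · 0.2 r/w`) represents jet fanning; temperature
  follows total-enthalpy conservation and pressure relaxes toward the
  background.  This profile is qualitative plumbing, parameterized and
  overridable.

### Particle transport

Droplets and ions obey linear drag `dv/dt = (u − v)/τ + a` with
`τ = ρ_p d² C_c(Kn)/(18 μ)`, `Kn = 2λ/d`, and the Cunningham slip
correction `C_c = 1 + Kn(1.257 + 0.4 e^{−1.1/Kn})`, which spans the
continuum (micron droplets near the nozzle) to free-molecular (2.2 nm ions
in the rarefied jet) regimes.  The integrator is the **exponential update**
`v' = u_eff + (v − u_eff) e^{−Δt/τ}` (with `u_eff = u + aτ`), exact for
locally constant gas: unconditionally stable for stiff drag, and it
degrades gracefully to the ballistic limit as τ → ∞ via `expm1`.  It was
chosen over semi-implicit Euler because it removes the O(Δt/τ) bias of that
scheme at no cost — the uniform-flow relaxation test then agrees with the
closed-form exponential essentially to machine precision.  The default
step is τ/20 clamped to [1 ns, 1 μs].  Brownian velocity kicks with
per-axis variance `2 k_B T Δt/(m τ)` are on for particles below 100 nm and
off otherwise (overridable).  Coupling is one-way: particles do not modify
the gas.  Droplet evaporation in flight is omitted (fixed diameters).

### Impact declustering

The yield of secondary ions per droplet impact is a **declared smooth
model**, not a first-principles prediction — no public formula exists for
it:

    Y(T_s, v) = Y_max · σ((T_s − T50)/ΔT) · exp(−(T_s/T_deg)^p),
    T50 = T50_ref − α v²

with shipped constants `Y_max = 0.9`, `T50_ref = 700 K`, `ΔT = 80 K`,
`α = 10⁻³ K/(m/s)²`, `T_deg = 1600 K`, `p = 4`.  The logistic term is
thermal activation of cluster breakup (faster impacts need less surface
heat); the power-law exponential is thermal degradation of the analyte.
The constants are calibrated so the net curve has a single interior optimum
between 800 and 1200 K — a regression target expressing the known behavior
of heated-surface declustering, honestly labeled as such.  Each successful
impact emits one singly charged 1 kDa ion of 2.2 nm diameter with a
cosine-law direction about the surface normal and a Maxwell speed at the
surface temperature.

### From surface to ion guide

The mechanistically load-bearing part of the geometry question is whether
ions formed on the surface survive to the guide.  Three declared model
components govern this:

1. **Entrainment around the obstacle.**  The near-surface gas is the
   unperturbed jet state at the surface position with a closed-form
   obstacle correction: incompressible potential flow for the sphere
   (tangential slip `(3/2) U sinθ` at the surface, impermeable wall),
   axisymmetric stagnation flow onto a finite disk for the plane (with a
   dead wake behind it); the cone reuses the sphere solution at equal
   radius.
2. **Hot-surface re-emission.**  A secondary ion that touches the heated
   surface is thermally re-emitted (fresh cosine draw at `T_s`) rather than
   adsorbed — the surface is hot precisely to prevent deposition.  Ions
   therefore skate around the obstacle along the slip flow.
3. **Recondensation in the cold jet.**  An ion exposed to gas below 200 K
   is lost with hazard rate `k ρ_gas` (`k = 1.5·10⁸ s⁻¹ per kg·m⁻³`):
   inside the supersonic zone the expansion-cooled, still-dense gas
   recondenses analyte ions back onto clusters, undoing the declustering.
   Downstream of the Mach disk the shock-reheated gas (≈291 K) is safe.
   This is the mechanism that makes placements *upstream* of the Mach disk
   unproductive and "just behind the Mach disk" optimal.

The extraction field (3000 V/m) acts only past the obstacle's equator (the
surface shields the upstream region).  The ion guide itself is an effective
model of a ring-electrode device: DC axial field `E_z = 3000 V/m`, radial
harmonic pseudopotential of depth `U* = 2 V` across an aperture
`r0 = 2.5 mm`, drag against quiescent nitrogen at 100 Pa / 300 K over a
10 mm length.  Captured means crossing the exit inside the aperture.  RF
phase dynamics, space charge and fringe fields are out of scope.

The plane target defaults to a **3 mm disk — larger than the guide
aperture**.  Ions can leave a flat face only around its rim, so they arrive
outside the 2.5 mm aperture and are lost: a wide flat target geometrically
shadows the inlet.  This is the model's reason a sphere outperforms a
plane; a plate small enough not to shadow the aperture would no longer
approximate a plane.

### The sweep

`run_sweep` evaluates shape × position × temperature cells with a common
seeded droplet population (common random numbers across cells), attributing
each cell's end-to-end efficiency as impact fraction × mean yield × escape
× capture, and `find_optimum` is a grid argmax with deterministic
tie-breaking (smaller z, cooler surface, sphere < plane < cone).  The
shipped grids are 2–12 mm (7 positions), 400–1500 K (6 temperatures),
sphere + plane, 2000 droplets per cell — small enough to run in about two
minutes on one core while leaving the Monte Carlo noise well below the
contrasts of interest.  At the defaults the optimum lands on the sphere at
6 mm (Mach disk: 5.22 mm) and 800 K, with upstream cells killed by
recondensation and far cells eroded by droplet beam spread and slow
post-shock deceleration.  These are calibrated regression properties of
the shipped defaults, not predictions about any particular instrument.

## 2. The aerosol and dose generators

Droplet populations are lognormal (median 0.8 μm, geometric SD 1.6, unit
density), launched 0.1 mm downstream of the exit across a 0.3 mm disk with
the local gas velocity plus 30 m/s isotropic jitter.  Micron medians
reflect the cluster sizes characteristic of ambient laser ablation; the
launch plane and jitter are calibrated defaults that set the impact-speed
scale (≈300 m/s at the Mach disk) and the beam divergence.  Laser dose
arithmetic is exact bookkeeping: average power = pulse energy × repetition
rate (12 nJ at 8.3 MHz → 99.6 mW ≈ 100 mW), fluence = energy / spot area
(12 nJ on a 10 μm spot → 0.0153 J/cm²).

## 3. The spectral phantom

The phantom emulates the data features the statistics wing must survive:

* class stick spectra built from the package's annotation table (adenine,
  guanine, glutamine, glutamate, PE 36:1/36:2/38:4, TG 52:2 [M+Cl]⁻) plus
  30 filler peaks on distinct 0.1 Da bins; PE lipids and nucleobases run
  high in the tumor-like class, the TG in the fibrous class;
* **planted differential bins**: all tumor-vs-normal mean differences are
  confined to a recorded set of bins at a single fold change (default 4×),
  so volcano recovery can be scored exactly;
* a lock-mass peak at exactly 554.2615 in every scan, scaled by the drift;
* multiplicative lognormal noise (σ = 0.3), a small additive baseline that
  vanishes with the noise level, a slow sinusoidal mass drift (±30 ppm
  across the raster) and, for the diathermy modality, a dataset-level
  per-peak lognormal gain (σ = 0.1) with wider noise (σ = 0.4);
* a labeled 2-D layout (stripes / nested / blobs) scanned in unidirectional
  row-major order.

What it does **not** emulate: isotope envelopes, profile-mode peak shapes,
chimeric/background peaks, spatial intensity gradients, specimen-level
biological variance, or class overlap.  Consequently the phantom benchmarks
(perfect confusion matrices, exact volcano recovery, ≥85% cross-modality
transfer) demonstrate that the pipeline is *correct and leak-free*, not
that real tissue would classify at these rates: clinical performance
depends on patient data this package does not model.  Where real data has
few specimens, the cross-validation should be run with `groups=` (specimen
ids) so pixels of one specimen never straddle a split; that is the default
whenever groups are provided.

## 4. Preprocessing and statistics choices

* **Lock-mass correction** is single-point multiplicative (most intense
  peak within ±0.5 Da of 554.2615; factor = reference/observed), with the
  last valid factor carried forward across lock-less scans.  The reference
  554.2615 is an instrument calibration constant used verbatim; the isotope
  arithmetic for C28H37N5O7 [M−H]⁻ gives 554.2620 and the table keeps the
  computed value — the two are deliberately not forced to agree.  The same
  policy holds for species whose commonly printed values differ from the
  isotope-sum in the last decimal (TG 52:2 [M+Cl]⁻ computes to 893.74,
  PE 36:1 to 744.55).
* **Binning** is half-open `[lo, lo + 0.1)` over 50–1200 m/z, bins named by
  their lower edge, intensities summed (not averaged), totals conserved
  exactly; values within a relative 10⁻⁶ of an upper boundary snap up so
  the decimal convention survives binary floating point.
* **Adduct arithmetic**: [M−H]⁻ removes a proton (electron retained),
  [M+Cl]⁻ adds Cl plus an electron, [M+H]⁺ adds a proton; atomic masses
  from a small in-repo CODATA/AME table.
* **PCA** is mean-centering + SVD (Gram-matrix shortcut when samples <
  bins), component signs fixed by making the largest-magnitude loading
  positive; **LDA** solves the symmetric generalized eigenproblem of
  between- vs within-class scatter on the top-k scores, the within-scatter
  ridged by `10⁻⁶·trace`; classification is nearest centroid in
  discriminant space.  `k` defaults to 10, capped at samples − classes.
* **"Leave-20%-out"** is read literally as repeated stratified random
  80/20 splits (25 repeats, pooled confusion) rather than 5-fold; at small
  sample counts this averages away split luck.
* **Volcano**: log2 of group-mean ratio (ε = 10⁻¹² zero protection),
  two-sided Mann–Whitney U per bin, Benjamini–Hochberg adjustment;
  significant iff q < 0.05 and |log2FC| > 1.  The rank test was chosen
  because TIC-normalized bin intensities are heavy-tailed and
  heteroscedastic; constant bins get p = 1.  The hyperspectral correlation
  map uses Pearson correlation against the reference-region mean spectrum
  (a simplification; other kernels exist).

## 5. Numerical details and degenerate inputs

Zero-diameter particles are ballistic (τ = 0 means instant equilibration
with the gas; τ = ∞ is handled through `expm1`).  A zero-length segment
cannot impact; cone intersections bisect to 10⁻¹² m; a subcritical pressure
ratio raises rather than returning a fictitious Mach disk; an all-zero
spectrum cannot be TIC-normalized; capture statistics use Wilson 95%
intervals (correct coverage at small counts, never outside [0, 1]).  All
generators and simulations are pure functions of (spec, seed); sweep cells
reuse one droplet transport per (shape, z) since temperature does not act
on the droplet phase.

## 6. Known limitations

The gas model is analytic and calibrated, not a DSMC/Navier–Stokes
solution; the declustering yield and the three near-surface components are
effective models with tunable constants; the guide is an effective
pseudopotential; droplet charge, evaporation and coagulation are ignored.
The simulator's claims are therefore *relative and mechanistic* (where the
optimum sits, which shape wins, why) — the absolute efficiencies have no
calibrated physical meaning.
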