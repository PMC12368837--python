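"""Synthetic inputs for both wings of the package.

The simulator wing consumes lognormal aerosol droplet populations launched
into the free jet; the statistics wing consumes class-structured REIMS
spectra with known ground truth.  The spectral generator emulates the
features of real tissue REIMS data that the analysis pipeline has to cope
with -- multiplicative lognormal intensity noise, slow ppm-scale mass drift
(exercising lock-mass correction), modality-specific per-peak gain (laser vs
electrosurgical diathermy sampling of the same tissue), and spatially
structured 2-D phantoms with tumor / normal / fibrous regions -- while
remaining a stick-spectrum model: no isotope envelopes, no profile-mode peak
shapes, no ablation chemistry.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classify import FeatureMatrix
from .jet_flow import FlowField
from .msi_pipeline import (DEFAULT_BIN_WIDTH, DEFAULT_MZ_RANGE, LOCK_MASS_MZ,
                           ImageGrid, ScanStream, Spectrum, bin_spectrum,
                           default_annotation_table, tic_normalize)
from .particle_transport import ParticleEnsemble

__all__ = [
    "AerosolSpec",
    "PhantomTruth",
    "laser_dose",
    "gen_aerosol",
    "gen_phantom",
    "gen_msi_dataset",
    "gen_bulk_spectra",
    "feature_matrix_from_grid",
    "DEFAULT_CLASSES",
]

DEFAULT_CLASSES = ("tumor", "normal", "fibrous")


# ---------------------------------------------------------------------------
# laser dose arithmetic
# ---------------------------------------------------------------------------

def laser_dose(pulse_energy: float, rep_rate: float,
               spot_diameter: float | None = None) -> dict:
    """Average power and per-pulse fluence of a pulsed ablation laser.

    ``average_power`` = pulse energy x repetition rate (W); ``fluence`` =
    pulse energy / spot area in J/cm^2 (None when no spot diameter is given).
    """
    if pulse_energy < 0 or rep_rate < 0:
        raise ValueError("energy and repetition rate must be non-negative")
    power = pulse_energy * rep_rate
    fluence = None
    if spot_diameter is not None:
        if spot_diameter <= 0:
            raise ValueError("spot diameter must be positive to compute fluence")
        radius_cm = spot_diameter * 100.0 / 2.0
        fluence = pulse_energy / (math.pi * radius_cm**2)
    return {"average_power": power, "fluence": fluence}


# ---------------------------------------------------------------------------
# aerosol populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AerosolSpec:
    """Lognormal droplet population launched into the jet.

    Defaults (0.8 um median, GSD 1.6, unit density) describe micrometre-scale
    tissue-ablation droplets; launch speed is the local gas speed at the
    launch plane plus isotropic thermal jitter.  Declared defaults.
    """

    median_diameter: float = 0.8e-6   # m
    gsd: float = 1.6                  # geometric standard deviation
    material_density: float = 1000.0  # kg/m^3
    n: int = 2000
    launch_z: float = 1.0e-4          # m, launch plane
    launch_radius: float = 3.0e-4     # m, uniform disk of start radii
    thermal_jitter: float = 30.0      # m/s, isotropic velocity jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median_diameter <= 0:
            raise ValueError("median diameter must be positive")
        if self.gsd < 1:
            raise ValueError("geometric SD must be >= 1")
        if self.n < 0:
            raise ValueError("population size must be non-negative")


def gen_aerosol(spec: AerosolSpec, flow: FlowField) -> ParticleEnsemble:
    """Sample the droplet ensemble; reproducible for a fixed spec seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    diam = spec.median_diameter * np.exp(
        rng.standard_normal(n) * math.log(spec.gsd))
    mass = spec.material_density * math.pi / 6.0 * diam**3
    # uniform over the launch disk
    r = spec.launch_radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2.0 * math.pi
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                           np.full(n, spec.launch_z)])
    st = flow.state_arrays(pos[:, 2], r)
    vel = np.zeros((n, 3))
    with np.errstate(invalid="ignore"):
        cx = np.where(r > 0, np.cos(phi), 0.0)
        cy = np.where(r > 0, np.sin(phi), 0.0)
    vel[:, 0] = st["u_r"] * cx
    vel[:, 1] = st["u_r"] * cy
    vel[:, 2] = st["u_z"]
    vel += spec.thermal_jitter * rng.standard_normal((n, 3))
    return ParticleEnsemble(mass=mass, diameter=diam, charge=np.zeros(n),
                            position=pos, velocity=vel,
                            material_density=np.full(n, spec.material_density))


# ---------------------------------------------------------------------------
# tissue phantoms and spectra
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground truth of a synthetic MSI phantom.

    ``labels`` holds class indices into ``class_names`` per pixel;
    ``peak_mz`` / ``class_intensity`` define the per-class stick spectra;
    ``planted_bins`` lists the lower edges of every bin whose mean differs
    between tumor and normal (all at the planted fold change).
    """

    labels: np.ndarray                # (rows, cols) int
    class_names: tuple
    peak_mz: np.ndarray               # (m,)
    class_intensity: np.ndarray       # (C, m)
    planted_bins: np.ndarray          # bin lower edges (Da)
    planted_fold: float
    drift_ppm_amplitude: float
    noise_sigma: float
    seed: int
    pixel_size_um: float = 5.0

    @property
    def rows(self) -> int:
        return self.labels.shape[0]

    @property
    def cols(self) -> int:
        return self.labels.shape[1]

    def label_names(self) -> np.ndarray:
        return np.asarray(self.class_names, dtype=object)[self.labels]


def _layout(rows: int, cols: int, layout: str, n_classes: int,
            rng: np.random.Generator) -> np.ndarray:
    if layout == "stripes":
        if cols < n_classes:
            raise ValueError("grid too small for stripe layout")
        edges = np.linspace(0, cols, n_classes + 1).astype(int)
        lab = np.zeros((rows, cols), dtype=int)
        for c in range(n_classes):
            lab[:, edges[c]:edges[c + 1]] = c
        return lab
    if layout == "nested":
        if min(rows, cols) < 2 * n_classes:
            raise ValueError("grid too small for nested layout")
        lab = np.zeros((rows, cols), dtype=int)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        depth = np.minimum.reduce([rr, cc, rows - 1 - rr, cols - 1 - cc])
        step = max(1, min(rows, cols) // (2 * n_classes))
        return np.minimum(depth // step, n_classes - 1)
    if layout == "blobs":
        if rows * cols < 4 * n_classes:
            raise ValueError("grid too small for blob layout")
        centers = rng.random((3 * n_classes, 2)) * [rows, cols]
        center_cls = np.arange(3 * n_classes) % n_classes
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        d2 = ((rr[..., None] - centers[:, 0]) ** 2 +
              (cc[..., None] - centers[:, 1]) ** 2)
        return center_cls[np.argmin(d2, axis=-1)]
    raise ValueError(f"unknown layout {layout!r}")


def _class_profiles(class_names: tuple, seed: int, n_filler: int = 30,
                    planted_fold: float = 4.0,
                    base_intensity: float = 100.0):
    """Per-class stick spectra seeded from the built-in annotation table.

    Tumor-vs-normal differences are confined to the planted set (nucleobases
    and PE lipids high in tumor, a few filler peaks high in normal), all at
    ``planted_fold``; the fibrous class carries the TG signature.  Exact
    intensities are arbitrary configuration values.
    """
    rng = np.random.default_rng(seed)
    table = default_annotation_table()
    species = {row["name"]: row["theoretical_mz"]
               for _i, row in table.iterrows()
               if row["name"] != "leucine enkephalin"}
    mz = list(species.values())
    # filler peaks on distinct 0.1 Da bins away from the species
    taken = {round(v, 1) for v in mz} | {round(LOCK_MASS_MZ, 1)}
    filler = []
    while len(filler) < n_filler:
        cand = float(rng.uniform(80.0, 1000.0))
        key = round(cand, 1)
        if key not in taken:
            taken.add(key)
            filler.append(cand)
    peak_mz = np.array(mz + filler)
    names = list(species) + [f"filler{i}" for i in range(n_filler)]
    order = np.argsort(peak_mz)
    peak_mz = peak_mz[order]
    names = [names[i] for i in order]
    base = base_intensity * rng.lognormal(0.0, 0.5, size=len(peak_mz))
    idx = {n: i for i, n in enumerate(names)}
    n_cls = len(class_names)
    intensity = np.tile(base, (n_cls, 1))
    ci = {c: k for k, c in enumerate(class_names)}
    tumor_high = ["adenine", "guanine", "PE(36:1)", "PE(36:2)", "PE(38:4)",
                  "filler0", "filler1", "filler2"]
    normal_high = ["filler3", "filler4", "filler5"]
    planted = []
    if "tumor" in ci and "normal" in ci:
        for name in tumor_high:
            intensity[ci["tumor"], idx[name]] *= planted_fold
            planted.append(peak_mz[idx[name]])
        for name in normal_high:
            intensity[ci["normal"], idx[name]] *= planted_fold
            planted.append(peak_mz[idx[name]])
    if "fibrous" in ci:
        intensity[ci["fibrous"], idx["TG(52:2)"]] *= 4.0
        intensity[ci["fibrous"], idx["glutamine"]] *= 2.5
        intensity[ci["fibrous"], idx["filler6"]] *= 3.0
    planted_bins = np.unique(np.floor(np.array(planted) / DEFAULT_BIN_WIDTH)
                             * DEFAULT_BIN_WIDTH)
    return peak_mz, intensity, planted_bins


def gen_phantom(rows: int = 24, cols: int = 24, layout: str = "stripes",
                seed: int = 17, classes: tuple = DEFAULT_CLASSES,
                planted_fold: float = 4.0, noise_sigma: float = 0.3,
                drift_ppm_amplitude: float = 30.0) -> PhantomTruth:
    """Deterministic labeled phantom with class spectral profiles attached.

    Every class is present; raises when the grid is too small for the layout.
    """
    rng = np.random.default_rng(seed)
    labels = _layout(rows, cols, layout, len(classes), rng)
    present = np.unique(labels)
    if len(present) != len(classes):
        raise ValueError("grid too small: not every class is present")
    peak_mz, intensity, planted = _class_profiles(classes, seed,
                                                  planted_fold=planted_fold)
    return PhantomTruth(labels=labels, class_names=tuple(classes),
                        peak_mz=peak_mz, class_intensity=intensity,
                        planted_bins=planted, planted_fold=planted_fold,
                        drift_ppm_amplitude=drift_ppm_amplitude,
                        noise_sigma=noise_sigma, seed=seed)


_MODALITY_PRESETS = {
    # per-peak gain spread, multiplicative noise sigma
    "laser": (0.0, None),
    "diathermy": (0.1, 0.4),
}


def _modality_params(modality: str, modality_sigma, noise_sigma,
                     default_noise: float):
    if modality not in _MODALITY_PRESETS:
        raise ValueError(f"unknown modality {modality!r}")
    gain_sigma, noise_preset = _MODALITY_PRESETS[modality]
    if modality_sigma is None:
        modality_sigma = gain_sigma
    if noise_sigma is None:
        noise_sigma = noise_preset if noise_preset is not None else default_noise
    return modality_sigma, noise_sigma


def _spectrum_for(mz_base, base_int, drift, rng, noise_sigma, gain,
                  lock_intensity, baseline_scale, scan_index, modality):
    mz = np.concatenate([mz_base, [LOCK_MASS_MZ]]) * (1.0 + drift)
    inten = base_int * gain * rng.lognormal(0.0, noise_sigma, size=len(base_int))
    inten = inten + np.abs(rng.normal(0.0, baseline_scale, size=len(base_int)))
    inten = np.concatenate([inten, [lock_intensity]])
    order = np.argsort(mz)
    return Spectrum(mz=mz[order], intensity=inten[order],
                    metadata={"scan_index": scan_index, "modality": modality})


def gen_msi_dataset(truth: PhantomTruth, modality: str = "laser",
                    modality_sigma: float | None = None,
                    noise_sigma: float | None = None,
                    seed: int | None = None) -> tuple[ScanStream, dict]:
    """Raster scan stream over the phantom, plus the recovery ground truth.

    Each pixel's spectrum is the class stick profile plus a lock-mass peak,
    under multiplicative lognormal noise, a small additive baseline, a slow
    sinusoidal ppm drift over scan index, and (for the diathermy modality) a
    dataset-level per-peak lognormal gain.
    """
    modality_sigma, noise_sigma = _modality_params(
        modality, modality_sigma, noise_sigma, truth.noise_sigma)
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gain_rng = np.random.default_rng(
        (seed * 2654435761 + sum(map(ord, modality))) % (2**31))
    gain = (gain_rng.lognormal(0.0, modality_sigma, size=len(truth.peak_mz))
            if modality_sigma > 0 else np.ones(len(truth.peak_mz)))
    n_scans = truth.rows * truth.cols
    flat_labels = truth.labels.reshape(-1)
    lock_intensity = 50.0 * float(truth.class_intensity.mean())
    # additive baseline scales with the noise level so the noise-free limit
    # is exactly deterministic
    baseline = 0.033 * noise_sigma * float(np.median(truth.class_intensity))
    drift = truth.drift_ppm_amplitude * 1e-6 * np.sin(
        2.0 * math.pi * np.arange(n_scans) / max(n_scans, 1))
    spectra = []
    for i in range(n_scans):
        cls = flat_labels[i]
        spectra.append(_spectrum_for(
            truth.peak_mz, truth.class_intensity[cls], drift[i], rng,
            noise_sigma, gain, lock_intensity, baseline, i, modality))
    stream = ScanStream(spectra=spectra, rows=truth.rows, cols=truth.cols,
                        pixel_size_um=truth.pixel_size_um)
    info = {"labels": truth.label_names().reshape(-1),
            "planted_bins": truth.planted_bins,
            "drift": drift, "modality": modality}
    return stream, info


def gen_bulk_spectra(classes: tuple = DEFAULT_CLASSES, n_per_class: int = 40,
                     modality: str = "laser", seed: int = 17,
                     modality_sigma: float | None = None,
                     noise_sigma: float | None = None,
                     planted_fold: float = 4.0,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     mz_range: tuple = DEFAULT_MZ_RANGE) -> FeatureMatrix:
    """Bulk (non-spatial) feature matrix under the same generative model.

    The base intensity draws depend only on ``seed``, so two modalities
    generated at the same seed differ exactly by the modality gain and noise
    width (identical matrices at ``modality_sigma = 0`` and equal noise).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    modality_sigma, noise_sigma = _modality_params(
        modality, modality_sigma, noise_sigma, 0.3)
    peak_mz, intensity, _planted = _class_profiles(classes, seed,
                                                   planted_fold=planted_fold)
    rng = np.random.default_rng(seed + 1)
    gain_rng = np.random.default_rng(
        (seed * 2654435761 + sum(map(ord, modality))) % (2**31))
    gain = (gain_rng.lognormal(0.0, modality_sigma, size=len(peak_mz))
            if modality_sigma > 0 else np.ones(len(peak_mz)))
    lock_intensity = 50.0 * float(intensity.mean())
    rows, labels, modalities = [], [], []
    n_bins = int(round((mz_range[1] - mz_range[0]) / bin_width))
    for ci, cls in enumerate(classes):
        for _ in range(n_per_class):
            spec = _spectrum_for(
                peak_mz, intensity[ci], 0.0, rng, noise_sigma, gain,
                lock_intensity,
                0.033 * noise_sigma * float(np.median(intensity)),
                len(labels), modality)
            rows.append(tic_normalize(bin_spectrum(spec, width=bin_width,
                                                   mz_range=mz_range)))
            labels.append(cls)
            modalities.append(modality)
    edges = mz_range[0] + bin_width * np.arange(n_bins)
    return FeatureMatrix(X=np.array(rows), labels=np.array(labels),
                         bin_edges=edges, modality=np.array(modalities))


def feature_matrix_from_grid(grid: ImageGrid, labels: np.ndarray,
                             modality: str | None = None,
                             groups: np.ndarray | None = None) -> FeatureMatrix:
    """Flatten a reconstructed image grid into a labeled feature matrix."""
    labels = np.asarray(labels).reshape(-1)
    flat = grid.flatten()
    if len(labels) != len(flat):
        raise ValueError("one label per pixel required")
    modal = np.full(len(flat), modality) if modality is not None else None
    return FeatureMatrix(X=flat, labels=labels, bin_edges=grid.bin_edges,
                         modality=modal, groups=groups)
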