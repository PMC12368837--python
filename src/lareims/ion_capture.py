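"""Secondary-ion capture: from the collision surface into the ion guide.

The ring-electrode ion guide (a StepWave-like device) is abstracted as a DC
axial gradient ``E_z`` plus a radial harmonic pseudopotential well of depth
``U*`` (potential U* (r/r0)^2), with drag against a uniform background gas at
the guide pressure.  An ion is captured when it crosses the guide exit inside
the aperture radius and lost when it reaches the aperture wall first.

Getting from the surface to the guide is the mechanistically interesting
part, so the module also provides a near-surface escape model used by the
geometry sweep:

* the gas flows around the obstacle (closed-form potential flow for the
  sphere, axisymmetric stagnation flow for the finite disk), entraining the
  emitted ions around the target;
* ions that touch the hot surface are thermally re-emitted (cosine law at the
  surface temperature) rather than adsorbed;
* ions exposed to cold (below a recondensation threshold), dense gas -- i.e.
  released inside the supersonic zone upstream of the Mach disk -- are lost
  by recondensation with a density-scaled hazard rate.

All three components are declared model choices with calibrated constants;
see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .constants import BOLTZMANN, ELEMENTARY_CHARGE
from .impact_declustering import (CollisionSurface, SecondaryIonSpec,
                                  detect_impacts, sample_emission_velocities,
                                  surface_normal)
from .jet_flow import Gas, GasState, NITROGEN, mean_free_path
from .particle_transport import (_relaxation_time_arrays, exp_drag_step)

__all__ = [
    "IonGuide",
    "CaptureSummary",
    "SurfaceRegionModel",
    "uniform_background",
    "trace_ion",
    "trace_ions_guide",
    "trace_surface_escape",
    "capture_efficiency",
    "obstacle_flow_velocity",
]


def uniform_background(pressure: float = 100.0, temperature: float = 300.0,
                       gas: Gas = NITROGEN) -> GasState:
    """Quiescent uniform gas state (used as the in-guide background)."""
    rho = pressure / (gas.specific_gas_constant * temperature)
    lam = mean_free_path(pressure, temperature, gas.molecular_diameter)
    return GasState(mach_number=0.0, temperature=temperature, density=rho,
                    pressure=pressure, velocity=(0.0, 0.0), mean_free_path=lam)


@dataclass(frozen=True)
class IonGuide:
    """DC gradient + radial pseudopotential abstraction of the ion guide.

    Defaults are declared values, not taken from any instrument drawing.
    """

    entrance_z: float = 9.0e-3       # m
    exit_z: float = 19.0e-3          # m
    inner_radius: float = 2.5e-3     # m
    axial_field: float = 3000.0      # V/m
    pseudopotential_depth: float = 2.0   # V
    background: GasState = field(default_factory=uniform_background)
    gas: Gas = NITROGEN

    def __post_init__(self) -> None:
        if self.exit_z <= self.entrance_z:
            raise ValueError("guide exit must lie downstream of entrance")
        if self.inner_radius <= 0:
            raise ValueError("guide aperture must be positive")
        if self.pseudopotential_depth < 0:
            raise ValueError("pseudopotential depth must be non-negative")


@dataclass(frozen=True)
class CaptureSummary:
    n_emitted: int
    n_captured: int
    efficiency: float
    ci95: tuple[float, float]

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"n_emitted": self.n_emitted,
                       "n_captured": self.n_captured,
                       "efficiency": self.efficiency,
                       "ci95": list(self.ci95)}, fh)


@dataclass(frozen=True)
class SurfaceRegionModel:
    """Calibrated constants of the near-surface escape model."""

    recondensation_temperature: float = 200.0   # K: hazard active below this
    recondensation_coefficient: float = 1.5e8   # 1/s per (kg/m^3)
    extraction_field: float = 3000.0            # V/m, applied past the obstacle
    wall_radius: float = 6.0e-3                 # m, radial loss boundary
    upstream_margin: float = 8.0e-3             # m, axial loss boundary
    t_max: float = 1.2e-4                       # s
    dt_max: float = 1.0e-7                      # s


def capture_efficiency(fates) -> CaptureSummary:
    """Capture fraction of an ensemble of fate strings with a Wilson 95% CI."""
    fates = list(fates)
    if not fates:
        raise ValueError("empty ensemble")
    n = len(fates)
    k = sum(f == "captured" for f in fates)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return CaptureSummary(n_emitted=n, n_captured=k, efficiency=k / n,
                          ci95=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# guide tracing
# ---------------------------------------------------------------------------

def trace_ions_guide(position: np.ndarray, velocity: np.ndarray,
                     mass: np.ndarray, charge: np.ndarray, diameter: np.ndarray,
                     material_density: np.ndarray, guide: IonGuide,
                     seed: int = 0, dt: float | None = None,
                     t_max: float = 2e-3, brownian: bool = True) -> np.ndarray:
    """Vectorized guide trace; returns fate strings per ion."""
    if np.any(charge == 0):
        raise ValueError("ion guide requires charge")
    n = len(mass)
    rng = np.random.default_rng(seed)
    pos = np.array(position, dtype=float).reshape(n, 3)
    vel = np.array(velocity, dtype=float).reshape(n, 3)
    bg = guide.background
    tau = _relaxation_time_arrays(np.asarray(material_density, float),
                                  np.asarray(diameter, float),
                                  bg.mean_free_path, guide.gas.viscosity)
    q = np.asarray(charge, float) * ELEMENTARY_CHARGE
    m = np.asarray(mass, float)
    if dt is None:
        finite = tau[np.isfinite(tau) & (tau > 0)]
        dt = float(np.clip((finite.min() / 8.0) if finite.size else 1e-8,
                           1e-10, 1e-7))
    k_rad = 2.0 * guide.pseudopotential_depth / guide.inner_radius**2  # V/m^2
    sig1 = np.sqrt(2.0 * BOLTZMANN * bg.temperature * dt /
                   (m * np.where(tau > 0, tau, np.inf)))
    fate = np.array(["active"] * n, dtype=object)
    t = 0.0
    active = np.ones(n, dtype=bool)
    while active.any() and t < t_max:
        idx = np.flatnonzero(active)
        p, v = pos[idx], vel[idx]
        acc = np.zeros_like(p)
        acc[:, 2] = q[idx] * guide.axial_field / m[idx]
        acc[:, 0] -= q[idx] * k_rad * p[:, 0] / m[idx]
        acc[:, 1] -= q[idx] * k_rad * p[:, 1] / m[idx]
        v_new = exp_drag_step(v, 0.0, acc, tau[idx, None], dt)
        if brownian:
            v_new = v_new + sig1[idx, None] * rng.standard_normal((len(idx), 3))
        p_new = p + 0.5 * (v + v_new) * dt
        pos[idx], vel[idx] = p_new, v_new
        r = np.hypot(p_new[:, 0], p_new[:, 1])
        lost = r >= guide.inner_radius
        captured = (~lost) & (p_new[:, 2] >= guide.exit_z)
        fate[idx[lost]] = "lost_wall"
        fate[idx[captured]] = "captured"
        active[idx] = ~(lost | captured)
        t += dt
    fate[fate == "active"] = "timed_out"
    return fate.astype(str)


def trace_ion(ion, guide: IonGuide, rng_seed: int = 0,
              dt: float | None = None, t_max: float = 2e-3) -> str:
    """Trace a single ion through the guide; returns its fate.

    Drag against the uniform guide background gas, axial force q E_z and the
    radial pseudopotential restoring force -2 q U* r / r0^2.  Captured iff the
    ion crosses ``exit_z`` with r < r0; lost if it reaches the aperture wall.
    """
    if ion.charge == 0:
        raise ValueError("ion guide requires charge")
    fates = trace_ions_guide(ion.position[None], ion.velocity[None],
                             np.array([ion.mass]), np.array([ion.charge]),
                             np.array([ion.diameter]),
                             np.array([ion.material_density]),
                             guide, seed=rng_seed, dt=dt, t_max=t_max)
    return str(fates[0])


# ---------------------------------------------------------------------------
# near-surface escape
# ---------------------------------------------------------------------------

def obstacle_flow_velocity(points: np.ndarray, surface: CollisionSurface,
                           free_stream_speed: float) -> np.ndarray:
    """Gas velocity near the collision surface for a uniform approach flow.

    Sphere: incompressible potential flow around a sphere (exact closed
    form).  Plane: axisymmetric stagnation flow onto a finite disk with a
    dead wake behind it.  Cone: approximated by the sphere solution of equal
    characteristic radius.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = np.zeros_like(pts)
    big_u = float(free_stream_speed)
    if surface.shape == "plane":
        rad = np.hypot(pts[:, 0], pts[:, 1])
        delta = surface.characteristic_radius
        zs = surface.axial_position
        h = zs - pts[:, 2]
        upstream = h > 0
        inside = rad <= surface.characteristic_radius
        near = upstream & inside & (h < delta)
        far = upstream & (~inside | (h >= delta))
        u[far, 2] = big_u
        u[near, 2] = big_u * h[near] / delta
        ur = big_u * rad / (2.0 * delta) * np.maximum(0.0, 1.0 - h / delta)
        safe = np.where(rad > 0, rad, 1.0)
        u[near, 0] = ur[near] * pts[near, 0] / safe[near]
        u[near, 1] = ur[near] * pts[near, 1] / safe[near]
        wake = ~upstream & ~inside
        u[wake, 2] = big_u
        return u
    # sphere (and cone approximated as a sphere)
    c = np.array([0.0, 0.0,
                  surface.axial_position + surface.characteristic_radius])
    rel = pts - c
    s = np.linalg.norm(rel, axis=1)
    s_safe = np.where(s > 1e-12, s, 1e-12)
    shat = rel / s_safe[:, None]
    k = np.clip(surface.characteristic_radius / s_safe, 0.0, 1.0) ** 3
    u[:, 2] = big_u * (1.0 + 0.5 * k)
    u -= (1.5 * k * big_u * shat[:, 2])[:, None] * shat
    return u


def trace_surface_escape(points: np.ndarray, normals: np.ndarray,
                         surface: CollisionSurface, local_state: dict,
                         spec: SecondaryIonSpec, guide: IonGuide,
                         model: SurfaceRegionModel | None = None,
                         seed: int = 0, gas: Gas = NITROGEN) -> dict:
    """Trace freshly emitted ions out of the surface region.

    ``local_state`` is the unperturbed jet state at the surface position
    (keys ``u`` axial speed, ``T``, ``rho``, ``lam``); phase ends when an ion
    clears the downstream edge of the obstacle (handing over to the guide
    trace), or the ion is lost to recondensation, to the walls, upstream, or
    by timeout.  Returns escaped positions/velocities and per-ion status.
    """
    model = model or SurfaceRegionModel()
    rng = np.random.default_rng(seed)
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    n = len(pts)
    if n == 0:
        return {"position": pts, "velocity": pts.copy(),
                "status": np.array([], dtype=str)}
    vel = sample_emission_velocities(normals, surface.temperature,
                                     spec.mass, rng)
    pts = pts + 1e-8 * np.atleast_2d(normals)
    mass = np.full(n, spec.mass)
    dens = np.full(n, spec.material_density)
    diam = np.full(n, spec.diameter)
    tau = _relaxation_time_arrays(dens, diam, local_state["lam"],
                                  gas.viscosity)
    tau0 = float(tau[0])
    dt = float(np.clip(tau0 / 5.0 if tau0 > 0 else model.dt_max,
                       2e-9, model.dt_max))
    cold = local_state["T"] < model.recondensation_temperature
    hazard = model.recondensation_coefficient * local_state["rho"] if cold else 0.0
    p_kill = -math.expm1(-hazard * dt)
    sig1 = np.sqrt(2.0 * BOLTZMANN * local_state["T"] * dt /
                   (mass * np.where(tau > 0, tau, np.inf)))
    if surface.shape == "plane":
        z_escape = surface.axial_position + 2e-4
    else:
        z_escape = surface.axial_position + 2.0 * surface.characteristic_radius
    q_over_m = spec.charge * ELEMENTARY_CHARGE / spec.mass
    status = np.array(["active"] * n, dtype=object)
    t = 0.0
    while (status == "active").any() and t < model.t_max:
        idx = np.flatnonzero(status == "active")
        p, v = pts[idx], vel[idx]
        u = obstacle_flow_velocity(p, surface, local_state["u"])
        acc = np.zeros_like(p)
        # extraction field acts only past the obstacle (shielded in front)
        past = p[:, 2] > surface.center_z
        acc[past, 2] = q_over_m * model.extraction_field
        v_new = exp_drag_step(v, u, acc, tau[idx, None], dt)
        v_new = v_new + sig1[idx, None] * rng.standard_normal((len(idx), 3))
        p_new = p + 0.5 * (v + v_new) * dt
        # hot-surface contact: thermal re-emission, not adsorption
        tpar, hitpts = detect_impacts(p, p_new, surface)
        hit = np.isfinite(tpar)
        if hit.any():
            hn = surface_normal(hitpts[hit], surface)
            v_new[hit] = sample_emission_velocities(
                hn, surface.temperature, spec.mass, rng)
            p_new[hit] = hitpts[hit] + 1e-8 * hn
        pts[idx], vel[idx] = p_new, v_new
        if p_kill > 0:
            dead = rng.random(len(idx)) < p_kill
            status[idx[dead]] = "recondensed"
        r = np.hypot(p_new[:, 0], p_new[:, 1])
        lost = (r > model.wall_radius) | \
               (p_new[:, 2] < surface.axial_position - model.upstream_margin) | \
               (p_new[:, 2] < 0)
        escaped = p_new[:, 2] > z_escape
        cur = status[idx]
        status[idx[(cur == "active") & lost]] = "lost_wall"
        sel = (status[idx] == "active") & escaped
        status[idx[sel]] = "escaped"
        t += dt
    status[status == "active"] = "timed_out"
    esc = status == "escaped"
    return {"position": pts[esc], "velocity": vel[esc],
            "status": status.astype(str)}
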