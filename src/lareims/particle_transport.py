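"""Stochastic particle transport through the free-jet flow field.

Droplets (micrometre scale) and secondary ions (nanometre scale) are moved by
Stokes drag with the Cunningham slip correction, which spans the continuum to
free-molecular regimes encountered along the expansion.  The velocity update
integrates the linear-drag equation

    dv/dt = (u_gas - v) / tau + a_ext

exactly over each step for locally constant gas (an exponential integrator),
which is unconditionally stable for arbitrarily stiff drag and reduces to the
ballistic limit as tau -> infinity.  Optional Brownian velocity kicks with
per-axis variance 2 kB T dt / (m tau) model thermal agitation of nanometre
particles.

Coordinates are 3-D Cartesian with the jet axis along z; the axisymmetric
flow field is queried at (z, r = hypot(x, y)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .constants import BOLTZMANN, DALTON
from .jet_flow import FlowField, GasState

__all__ = [
    "Particle",
    "ParticleEnsemble",
    "TrajectoryResult",
    "cunningham_correction",
    "knudsen_number",
    "relaxation_time",
    "simulate_trajectory",
    "advance_ensemble",
    "BROWNIAN_DIAMETER_THRESHOLD",
]

#: Brownian kicks default to on below this particle diameter (m).
BROWNIAN_DIAMETER_THRESHOLD = 100e-9


@dataclass
class Particle:
    """A droplet or ion with mechanical state.

    ``mass`` in kg (use ``Particle.from_daltons`` for molecular masses),
    ``charge`` in elementary charges.
    """

    mass: float
    diameter: float
    charge: int = 0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    material_density: float = 1000.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(3)
        if self.mass <= 0:
            raise ValueError("particle mass must be positive")
        if self.diameter < 0:
            raise ValueError("particle diameter must be non-negative")
        if self.material_density <= 0:
            raise ValueError("material density must be positive")

    @classmethod
    def from_daltons(cls, mass_da: float, **kw) -> "Particle":
        return cls(mass=mass_da * DALTON, **kw)

    @classmethod
    def droplet(cls, diameter: float, material_density: float = 1000.0,
                **kw) -> "Particle":
        mass = material_density * math.pi / 6.0 * diameter**3
        return cls(mass=mass, diameter=diameter,
                   material_density=material_density, **kw)


@dataclass
class ParticleEnsemble:
    """Structure-of-arrays ensemble used by the vectorized integrators."""

    mass: np.ndarray          # (n,) kg
    diameter: np.ndarray      # (n,) m
    charge: np.ndarray        # (n,) elementary charges
    position: np.ndarray      # (n, 3) m
    velocity: np.ndarray      # (n, 3) m/s
    material_density: np.ndarray  # (n,) kg/m^3

    def __post_init__(self) -> None:
        n = len(self.mass)
        for name in ("mass", "diameter", "charge", "material_density"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(n))
        self.position = np.asarray(self.position, dtype=float).reshape(n, 3)
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(n, 3)

    def __len__(self) -> int:
        return len(self.mass)

    def to_particles(self) -> list[Particle]:
        return [Particle(mass=self.mass[i], diameter=self.diameter[i],
                         charge=int(self.charge[i]), position=self.position[i].copy(),
                         velocity=self.velocity[i].copy(),
                         material_density=self.material_density[i])
                for i in range(len(self))]


@dataclass
class TrajectoryResult:
    """Outcome of one simulated trajectory."""

    fate: str                       # impacted_surface | captured | lost_wall | timed_out
    impact_point: Optional[np.ndarray] = None
    impact_speed: Optional[float] = None
    path: Optional[np.ndarray] = None
    steps: int = 0

    def __post_init__(self) -> None:
        if (self.fate == "impacted_surface") != (self.impact_point is not None):
            raise ValueError("impact_point present iff fate == impacted_surface")


def cunningham_correction(kn):
    """Cunningham slip correction Cc = 1 + Kn (1.257 + 0.4 exp(-1.1/Kn)).

    Continuous at Kn = 0 where Cc = 1 (continuum limit).
    """
    kn = np.asarray(kn, dtype=float)
    if np.any(kn < 0):
        raise ValueError("Knudsen number must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(kn > 0, 1.1 / np.where(kn > 0, kn, 1.0), np.inf)
        cc = 1.0 + kn * (1.257 + 0.4 * np.exp(-inv))
    out = np.where(kn > 0, cc, 1.0)
    return float(out) if out.ndim == 0 else out


def knudsen_number(mean_free_path, diameter):
    """Kn = 2 lambda / d (particle radius convention)."""
    diameter = np.asarray(diameter, dtype=float)
    with np.errstate(divide="ignore"):
        kn = 2.0 * np.asarray(mean_free_path, dtype=float) / diameter
    return np.where(diameter > 0, kn, np.inf)


def relaxation_time(particle, gas: GasState):
    """Drag relaxation time tau = rho_p d^2 Cc(Kn) / (18 mu); 0 for d = 0."""
    d = particle.diameter
    if np.ndim(d) == 0 and d == 0:
        return 0.0
    kn = 2.0 * gas.mean_free_path / d
    cc = cunningham_correction(kn)
    mu = _gas_viscosity(gas)
    return particle.material_density * d * d * cc / (18.0 * mu)


def _gas_viscosity(gas) -> float:
    # GasState carries no viscosity; transport uses the carrier-gas default.
    return getattr(gas, "viscosity", 1.8e-5)


def _relaxation_time_arrays(material_density, diameter, lam, mu):
    d = np.asarray(diameter, dtype=float)
    kn = knudsen_number(lam, d)
    cc = cunningham_correction(np.where(np.isfinite(kn), kn, 1e12))
    tau = material_density * d * d * cc / (18.0 * mu)
    return np.where(d > 0, tau, 0.0)


def _tau_k(tau, dt):
    """Return (k, tau*k) with k = 1 - exp(-dt/tau), stable for tau in [0, inf]."""
    tau = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        x = np.where(tau > 0, dt / tau, np.inf)
    k = -np.expm1(-x)
    tk = np.where(tau > 0, tau * k, 0.0)
    tk = np.where(np.isfinite(tau), tk, dt)   # ballistic limit tau*k -> dt
    k = np.where(np.isfinite(tau), k, 0.0)
    return k, tk


def exp_drag_step(velocity, u_gas, accel, tau, dt):
    """One exact step of dv/dt = (u - v)/tau + a for locally constant u, a.

    Works elementwise; ``tau`` may be 0 (instant equilibration) or inf
    (ballistic).  Returns the updated velocity.
    """
    k, tk = _tau_k(tau, dt)
    return velocity + (u_gas - velocity) * k + accel * tk


def _gas_at(field_: FlowField, position: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gas velocity (n,3), temperature (n,), mean free path (n,) at positions."""
    x, y, z = position[:, 0], position[:, 1], position[:, 2]
    r = np.hypot(x, y)
    st = field_.state_arrays(np.clip(z, 0.0, None), r)
    u = np.zeros_like(position)
    u[:, 2] = st["u_z"]
    with np.errstate(invalid="ignore"):
        rhat_x = np.where(r > 0, x / np.where(r > 0, r, 1.0), 0.0)
        rhat_y = np.where(r > 0, y / np.where(r > 0, r, 1.0), 0.0)
    u[:, 0] = st["u_r"] * rhat_x
    u[:, 1] = st["u_r"] * rhat_y
    return u, st["T"], st["lam"]


def advance_ensemble(ensemble: ParticleEnsemble, field_: FlowField,
                     surface=None, seed: int = 0, dt: float | None = None,
                     t_max: float = 2e-4, brownian: bool | None = None,
                     accel: Callable[[np.ndarray], np.ndarray] | None = None,
                     mu: float | None = None) -> dict:
    """Advance every particle until impact, wall loss, or timeout.

    Returns a dict of arrays: ``fate`` (string codes), ``impact_point`` (n,3 with
    NaN where absent), ``impact_speed``, final ``position``/``velocity``, and
    ``time``.  Reproducible for a fixed ``seed``; the adaptive global step is
    tau_min/20 clamped to [1e-9, 1e-6] s.
    """
    from .impact_declustering import detect_impacts  # local import, no cycle

    n = len(ensemble)
    rng = np.random.default_rng(seed)
    mu = field_.source.gas.viscosity if mu is None else mu
    pos = ensemble.position.copy()
    vel = ensemble.velocity.copy()
    fate = np.array(["active"] * n, dtype=object)
    impact_point = np.full((n, 3), np.nan)
    impact_speed = np.full(n, np.nan)
    t_done = np.zeros(n)
    brown = (ensemble.diameter < BROWNIAN_DIAMETER_THRESHOLD) if brownian is None \
        else np.full(n, bool(brownian))
    t = 0.0
    active = fate == "active"
    while np.any(active) and t < t_max:
        idx = np.flatnonzero(active)
        p = pos[idx]
        v = vel[idx]
        u, temp, lam = _gas_at(field_, p)
        tau = _relaxation_time_arrays(ensemble.material_density[idx],
                                      ensemble.diameter[idx], lam, mu)
        if dt is None:
            pos_tau = tau[tau > 0]
            base = pos_tau.min() / 20.0 if pos_tau.size else 1e-7
            step = float(np.clip(base, 1e-9, 1e-6))
        else:
            step = dt
        a = accel(p) if accel is not None else 0.0
        v_new = exp_drag_step(v, u, a, tau[:, None], step)
        if np.any(brown[idx]):
            sig = np.sqrt(2.0 * BOLTZMANN * temp * step /
                          (ensemble.mass[idx] * np.where(tau > 0, tau, np.inf)))
            sig = np.where(brown[idx], sig, 0.0)
            v_new = v_new + sig[:, None] * rng.standard_normal((len(idx), 3))
        p_new = p + 0.5 * (v + v_new) * step
        # surface impact on the segment p -> p_new
        if surface is not None:
            tpar, pts = detect_impacts(p, p_new, surface)
            hit = np.isfinite(tpar)
            if np.any(hit):
                gi = idx[hit]
                fate[gi] = "impacted_surface"
                impact_point[gi] = pts[hit]
                impact_speed[gi] = np.linalg.norm(
                    v[hit] + tpar[hit, None] * (v_new[hit] - v[hit]), axis=1)
                t_done[gi] = t + step
        pos[idx] = p_new
        vel[idx] = v_new
        # domain walls
        r_new = np.hypot(p_new[:, 0], p_new[:, 1])
        out = (r_new > field_.r_max) | (p_new[:, 2] > field_.z_max) | (p_new[:, 2] < 0)
        out &= fate[idx] == "active"
        gi = idx[out]
        fate[gi] = "lost_wall"
        t_done[gi] = t + step
        t += step
        active = fate == "active"
    rem = fate == "active"
    fate[rem] = "timed_out"
    t_done[rem] = t
    return {"fate": fate.astype(str), "impact_point": impact_point,
            "impact_speed": impact_speed, "position": pos, "velocity": vel,
            "time": t_done}


def ensemble_to_csv(result: dict, path, seed: int | None = None) -> None:
    """Write an :func:`advance_ensemble` result as CSV, one row per particle."""
    import pandas as pd

    n = len(result["fate"])
    df = pd.DataFrame({
        "seed": np.full(n, seed if seed is not None else -1, dtype=int),
        "fate": result["fate"],
        "impact_speed": result["impact_speed"],
        "impact_x": result["impact_point"][:, 0],
        "impact_y": result["impact_point"][:, 1],
        "impact_z": result["impact_point"][:, 2],
        "time": result["time"],
    })
    df.to_csv(path, index=False)


def simulate_trajectory(particle: Particle, field_: FlowField, surface=None,
                        rng_seed: int = 0, dt: float | None = None,
                        t_max: float = 2e-4, brownian: bool | None = None,
                        record_path: bool = False,
                        path_stride: int = 10) -> TrajectoryResult:
    """Integrate a single particle through the flow field.

    Terminates on surface impact (recording the impact point and speed), wall
    loss, or ``t_max``.  Brownian kicks default to on for particles below
    100 nm diameter.  Bit-reproducible for a fixed ``rng_seed``; decorrelated
    ensembles can be built by seeding each particle index with seed + index.
    """
    if dt is not None and dt <= 0:
        raise ValueError("dt must be positive")
    if t_max <= (dt or 0):
        raise ValueError("t_max must exceed dt")
    z0 = particle.position[2]
    r0 = math.hypot(particle.position[0], particle.position[1])
    if not (0 <= z0 <= field_.z_max) or r0 > field_.r_max:
        raise ValueError("particle initialized outside flow-field domain")
    ens = ParticleEnsemble(
        mass=[particle.mass], diameter=[particle.diameter],
        charge=[particle.charge], position=[particle.position],
        velocity=[particle.velocity], material_density=[particle.material_density])
    path = [particle.position.copy()] if record_path else None
    # re-implement as stepwise loop to be able to record the path
    res = _simulate_single(ens, field_, surface, rng_seed, dt, t_max, brownian, path,
                           path_stride)
    return res


def _simulate_single(ens, field_, surface, seed, dt, t_max, brownian, path,
                     path_stride) -> TrajectoryResult:
    from .impact_declustering import detect_impacts

    rng = np.random.default_rng(seed)
    mu = field_.source.gas.viscosity
    pos = ens.position.copy()
    vel = ens.velocity.copy()
    brown = bool(ens.diameter[0] < BROWNIAN_DIAMETER_THRESHOLD) if brownian is None \
        else bool(brownian)
    t, steps = 0.0, 0
    while t < t_max:
        u, temp, lam = _gas_at(field_, pos)
        tau = _relaxation_time_arrays(ens.material_density, ens.diameter, lam, mu)
        if dt is None:
            step = float(np.clip(tau[0] / 20.0 if tau[0] > 0 else 1e-7, 1e-9, 1e-6))
        else:
            step = dt
        v_new = exp_drag_step(vel, u, 0.0, tau[:, None], step)
        if brown and tau[0] > 0:
            sig = math.sqrt(2.0 * BOLTZMANN * temp[0] * step / (ens.mass[0] * tau[0]))
            v_new = v_new + sig * rng.standard_normal((1, 3))
        p_new = pos + 0.5 * (vel + v_new) * step
        steps += 1
        if surface is not None:
            tpar, pts = detect_impacts(pos, p_new, surface)
            if np.isfinite(tpar[0]):
                speed = float(np.linalg.norm(vel[0] + tpar[0] * (v_new[0] - vel[0])))
                return TrajectoryResult(
                    fate="impacted_surface", impact_point=pts[0],
                    impact_speed=speed,
                    path=np.array(path) if path is not None else None, steps=steps)
        pos, vel = p_new, v_new
        if path is not None and steps % path_stride == 0:
            path.append(pos[0].copy())
        r = math.hypot(pos[0, 0], pos[0, 1])
        if r > field_.r_max or pos[0, 2] > field_.z_max or pos[0, 2] < 0:
            return TrajectoryResult(fate="lost_wall",
                                    path=np.array(path) if path is not None else None,
                                    steps=steps)
        t += step
    return TrajectoryResult(fate="timed_out",
                            path=np.array(path) if path is not None else None,
                            steps=steps)
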