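"""Droplet impact detection and surface-induced declustering.

Aerosol droplets accelerated by the free-jet expansion are impacted against a
heated collision surface, which breaks the clusters apart and liberates
secondary analyte ions (surface-induced declustering).  The yield model is a
declared smooth parameterization, not a first-principles prediction: a
logistic thermal activation (kinetic impact energy lowers the activation
midpoint) multiplied by a power-law thermal-degradation cutoff, giving a
single interior optimum in surface temperature.  The shipped constants are
calibrated so that the optimum lies near 1000 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import maxwell

from .constants import BOLTZMANN, DALTON
from .particle_transport import Particle

__all__ = [
    "CollisionSurface",
    "DeclusteringModel",
    "SecondaryIonSpec",
    "detect_impact",
    "detect_impacts",
    "surface_normal",
    "declustering_yield",
    "emit_secondary_ions",
    "sample_emission_velocities",
]

_SHAPES = ("sphere", "plane", "cone")
#: cone-surface bisection tolerance (m)
_CONE_TOL = 1e-12


@dataclass(frozen=True)
class CollisionSurface:
    """Axisymmetric collision target facing the incoming jet.

    ``axial_position`` is the z of the surface point nearest the capillary
    (sphere: front pole; plane: the disk plane; cone: the apex).  The plane is
    a finite disk of radius ``characteristic_radius``; the cone opens
    downstream with a 45 degree half-angle and axial extent equal to its
    characteristic radius.
    """

    shape: str = "sphere"
    characteristic_radius: float = 1.5e-3   # m
    axial_position: float = 6.0e-3          # m, from capillary exit
    temperature: float = 1000.0             # K

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.axial_position <= 0:
            raise ValueError("surface must sit downstream of the capillary exit")
        if self.temperature <= 0:
            raise ValueError("surface temperature must be positive")
        if self.characteristic_radius <= 0:
            raise ValueError("characteristic radius must be positive")

    @property
    def center_z(self) -> float:
        """Sphere center z (front pole + radius); apex/plane z otherwise."""
        if self.shape == "sphere":
            return self.axial_position + self.characteristic_radius
        return self.axial_position


@dataclass(frozen=True)
class DeclusteringModel:
    """Parameters of the impact-declustering yield curve (all in config)."""

    y_max: float = 0.9              # peak emission probability
    t50_ref: float = 700.0          # K, activation midpoint at zero speed
    dt: float = 80.0                # K, logistic width
    kinetic_coupling: float = 1e-3  # K per (m/s)^2, impact-speed shift of T50
    degradation_t: float = 1600.0   # K, thermal degradation scale
    degradation_power: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.y_max <= 1):
            raise ValueError("Y_max must be in (0, 1]")
        if self.dt <= 0:
            raise ValueError("logistic width dT must be positive")


@dataclass(frozen=True)
class SecondaryIonSpec:
    """Secondary ion produced by a successful declustering event.

    Defaults are the species the simulation wing is built around: singly
    charged 1 kDa ions of 2.2 nm diameter, emitted with a cosine-law
    direction about the surface normal at the surface temperature.
    """

    mass_da: float = 1000.0
    diameter: float = 2.2e-9
    charge: int = 1
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("secondary ion must carry charge")

    @property
    def mass(self) -> float:
        return self.mass_da * DALTON

    @property
    def material_density(self) -> float:
        return self.mass / (math.pi / 6.0 * self.diameter**3)


# ---------------------------------------------------------------------------
# impact detection
# ---------------------------------------------------------------------------

def detect_impacts(p0: np.ndarray, p1: np.ndarray,
                   surface: CollisionSurface) -> tuple[np.ndarray, np.ndarray]:
    """First intersection of segments ``p0 -> p1`` with the surface.

    Returns (t, points): the segment parameter in [0, 1] (NaN where there is
    no intersection) and the intersection points (NaN rows where absent).
    Sphere and plane are solved exactly; the cone by bisection to 1e-12 m.
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    if not (np.all(np.isfinite(p0)) and np.all(np.isfinite(p1))):
        raise ValueError("segment endpoints must be finite")
    n = len(p0)
    t = np.full(n, np.nan)
    if surface.shape == "sphere":
        c = np.array([0.0, 0.0, surface.center_z])
        rr = surface.characteristic_radius
        d = p1 - p0
        f = p0 - c
        a = np.einsum("ij,ij->i", d, d)
        b = 2.0 * np.einsum("ij,ij->i", f, d)
        cq = np.einsum("ij,ij->i", f, f) - rr * rr
        disc = b * b - 4.0 * a * cq
        ok = (disc >= 0) & (a > 0)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / (2.0 * a)
            t2 = (-b + sq) / (2.0 * a)
        for cand in (t1, t2):
            sel = ok & np.isnan(t) & (cand >= 0.0) & (cand <= 1.0)
            t[sel] = cand[sel]
    elif surface.shape == "plane":
        zs = surface.axial_position
        dz = p1[:, 2] - p0[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            cand = (zs - p0[:, 2]) / dz
        cross = (dz != 0) & (cand >= 0.0) & (cand <= 1.0)
        pts = p0 + cand[:, None] * (p1 - p0)
        within = np.hypot(pts[:, 0], pts[:, 1]) <= surface.characteristic_radius
        t[cross & within] = cand[cross & within]
    else:  # cone: r = z - z_apex on z in [z_apex, z_apex + R]
        t[:] = _cone_bisect(p0, p1, surface)
    pts = p0 + t[:, None] * (p1 - p0)
    return t, pts


def _cone_signed(p: np.ndarray, surface: CollisionSurface) -> np.ndarray:
    """Positive outside the cone surface, negative inside."""
    za = surface.axial_position
    r = np.hypot(p[:, 0], p[:, 1])
    axial = np.clip(p[:, 2] - za, 0.0, surface.characteristic_radius)
    return r - axial


def _cone_bisect(p0: np.ndarray, p1: np.ndarray,
                 surface: CollisionSurface) -> np.ndarray:
    za = surface.axial_position
    zb = za + surface.characteristic_radius
    n = len(p0)
    t = np.full(n, np.nan)
    f0 = _cone_signed(p0, surface)
    f1 = _cone_signed(p1, surface)
    inz = ((np.minimum(p0[:, 2], p1[:, 2]) <= zb) &
           (np.maximum(p0[:, 2], p1[:, 2]) >= za))
    hit = inz & (f0 > 0) & (f1 <= 0)
    if not np.any(hit):
        return t
    lo = np.zeros(hit.sum())
    hi = np.ones(hit.sum())
    a, b = p0[hit], p1[hit]
    seg = np.linalg.norm(b - a, axis=1)
    n_iter = int(np.ceil(np.log2(max(seg.max(), 1e-9) / _CONE_TOL))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        fm = _cone_signed(a + mid[:, None] * (b - a), surface)
        lo = np.where(fm > 0, mid, lo)
        hi = np.where(fm > 0, hi, mid)
    t[hit] = hi
    return t


def detect_impact(p0, p1, surface: CollisionSurface):
    """Scalar convenience wrapper: impact point or None for one segment."""
    t, pts = detect_impacts(np.asarray(p0)[None], np.asarray(p1)[None], surface)
    return pts[0] if np.isfinite(t[0]) else None


def surface_normal(points: np.ndarray, surface: CollisionSurface) -> np.ndarray:
    """Outward (upstream-facing) unit normal at surface points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if surface.shape == "sphere":
        c = np.array([0.0, 0.0, surface.center_z])
        v = pts - c
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    if surface.shape == "plane":
        n = np.zeros_like(pts)
        n[:, 2] = -1.0
        return n
    r = np.hypot(pts[:, 0], pts[:, 1])
    safe = np.where(r > 0, r, 1.0)
    n = np.column_stack([pts[:, 0] / safe, pts[:, 1] / safe, -np.ones(len(pts))])
    n[r == 0] = [0.0, 0.0, -1.0]
    return n / np.linalg.norm(n, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# yield and emission
# ---------------------------------------------------------------------------

def declustering_yield(model: DeclusteringModel, surface_temperature,
                       impact_speed):
    """Secondary-ion yield Y(T_s, v) in [0, Y_max].

    Y = Y_max sigma((T_s - T50)/dT) exp(-(T_s/T_deg)^p) with
    T50 = T50_ref - alpha v^2: hotter surfaces activate declustering until
    thermal degradation takes over, and faster impacts need less surface heat.
    """
    ts = np.asarray(surface_temperature, dtype=float)
    v = np.asarray(impact_speed, dtype=float)
    if np.any(ts <= 0):
        raise ValueError("surface temperature must be positive")
    if np.any(v < 0):
        raise ValueError("impact speed must be non-negative")
    t50 = model.t50_ref - model.kinetic_coupling * v * v
    act = expit((ts - t50) / model.dt)
    if math.isfinite(model.degradation_t):
        deg = np.exp(-np.power(ts / model.degradation_t, model.degradation_power))
    else:
        deg = 1.0
    out = model.y_max * act * deg
    return float(out) if out.ndim == 0 else out


def sample_emission_velocities(normals: np.ndarray, temperature: float,
                               ion_mass: float, rng: np.random.Generator) -> np.ndarray:
    """Cosine-law directions about the surface normals, Maxwell speeds at T_s."""
    normals = np.atleast_2d(normals)
    n = len(normals)
    u = rng.random(n)
    phi = rng.random(n) * 2.0 * math.pi
    ct = np.sqrt(u)                      # cosine-law polar angle
    st = np.sqrt(1.0 - u)
    # orthonormal frame around each normal
    ref = np.where(np.abs(normals[:, 2:3]) < 0.9,
                   np.tile([0.0, 0.0, 1.0], (n, 1)),
                   np.tile([1.0, 0.0, 0.0], (n, 1)))
    e1 = np.cross(normals, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)
    dirs = (ct[:, None] * normals +
            st[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    scale = math.sqrt(BOLTZMANN * temperature / ion_mass)
    speeds = maxwell.rvs(scale=scale, size=n, random_state=rng)
    return dirs * speeds[:, None]


def emit_secondary_ions(impact: dict, model: DeclusteringModel,
                        spec: SecondaryIonSpec, rng_seed: int = 0,
                        surface: CollisionSurface | None = None) -> list[Particle]:
    """Bernoulli emission of secondary ions for one impact.

    ``impact`` needs ``point`` (3,), ``speed`` (m/s) and either ``normal`` or a
    ``surface`` to compute it from.  With probability Y(T_s, speed) the event
    emits ``multiplicity`` ions (default 1) with the spec's mass, diameter and
    charge; otherwise the list is empty.  Reproducible for fixed seed.
    """
    point = np.asarray(impact["point"], dtype=float)
    speed = float(impact["speed"])
    if surface is not None:
        normal = surface_normal(point[None], surface)[0]
        temperature = surface.temperature
    else:
        normal = np.asarray(impact["normal"], dtype=float)
        temperature = float(impact["temperature"])
    rng = np.random.default_rng(rng_seed)
    y = declustering_yield(model, temperature, speed)
    if rng.random() >= y:
        return []
    vels = sample_emission_velocities(
        np.tile(normal, (spec.multiplicity, 1)), temperature, spec.mass, rng)
    offset = point + 1e-9 * normal
    return [Particle.from_daltons(spec.mass_da, diameter=spec.diameter,
                                  charge=spec.charge, position=offset,
                                  velocity=vels[i],
                                  material_density=spec.material_density)
            for i in range(spec.multiplicity)]
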