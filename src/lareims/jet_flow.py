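"""Continuum free-jet flow field of the atmospheric interface.

An underexpanded free jet forms behind the inlet capillary of the mass
spectrometer: gas expands from stagnation conditions (``P0``, ``T0``) into the
first vacuum stage at background pressure ``P1``, accelerates to supersonic
speed along the axis, and terminates in a normal shock (the Mach disk).  The
flow field built here serves as the background gas state for droplet and ion
transport; it is an engineering model, not a Navier-Stokes or DSMC solution:

* Mach-disk position from the standard empirical correlation
  ``x_M = 0.67 d sqrt(P0/P1)``.
* Centerline Mach number upstream of the Mach disk from the Ashkenas-Sherman
  far-field correlation, blended linearly to the sonic exit near the nozzle.
* Downstream of the Mach disk the gas is a uniform subsonic drift at the
  post-normal-shock (Rankine-Hugoniot) state.
* Off-axis decay by a Gaussian radial similarity profile whose half-width
  grows linearly with axial distance.

All state variables (T, rho, p) follow the isentropic relations from the
local Mach number upstream of the shock.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BOLTZMANN, GAS_CONSTANT

__all__ = [
    "Gas",
    "NITROGEN",
    "SourceConditions",
    "GasState",
    "FlowField",
    "SubcriticalExpansionError",
    "mach_disk_position",
    "centerline_state",
    "build_flow_field",
    "mean_free_path",
    "normal_shock_state",
]


class SubcriticalExpansionError(ValueError):
    """Raised when P0/P1 is below the critical ratio: no supersonic expansion."""


@dataclass(frozen=True)
class Gas:
    """Bulk properties of the carrier gas."""

    molar_mass: float          # kg/mol
    gamma: float               # heat capacity ratio, dimensionless
    viscosity: float           # Pa s
    molecular_diameter: float  # m

    @property
    def specific_gas_constant(self) -> float:
        return GAS_CONSTANT / self.molar_mass


#: Default carrier gas.  Calibrated defaults, not values from any instrument.
NITROGEN = Gas(molar_mass=0.028, gamma=1.4, viscosity=1.8e-5,
               molecular_diameter=3.7e-10)


@dataclass(frozen=True)
class SourceConditions:
    """Stagnation and background state of the free-jet expansion.

    Defaults describe an atmospheric inlet into a first vacuum stage and are
    calibrated so the Mach disk falls near 5 mm; they are declared defaults.
    """

    stagnation_pressure: float = 101325.0   # Pa
    background_pressure: float = 600.0      # Pa
    capillary_diameter: float = 0.6e-3      # m
    stagnation_temperature: float = 300.0   # K
    gas: Gas = NITROGEN

    def __post_init__(self) -> None:
        if not (self.stagnation_pressure > self.background_pressure > 0):
            raise ValueError("require P0 > P1 > 0")
        if self.capillary_diameter < 0:
            raise ValueError("capillary diameter must be non-negative")
        if self.stagnation_temperature <= 0:
            raise ValueError("stagnation temperature must be positive")
        if self.gas.gamma <= 1:
            raise ValueError("heat capacity ratio must exceed 1")

    @property
    def pressure_ratio(self) -> float:
        return self.stagnation_pressure / self.background_pressure

    @property
    def critical_ratio(self) -> float:
        g = self.gas.gamma
        return ((g + 1.0) / 2.0) ** (g / (g - 1.0))

    @property
    def stagnation_density(self) -> float:
        return self.stagnation_pressure / (
            self.gas.specific_gas_constant * self.stagnation_temperature)


@dataclass(frozen=True)
class GasState:
    """Local isentropic gas state at a point of the flow field."""

    mach_number: float
    temperature: float        # K
    density: float            # kg/m^3
    pressure: float           # Pa
    velocity: tuple           # (u_z, u_r) m/s
    mean_free_path: float     # m


def mean_free_path(pressure: float, temperature: float, molecular_diameter: float):
    """Hard-sphere kinetic-theory mean free path, lambda = kT / (sqrt2 pi d^2 p)."""
    return BOLTZMANN * temperature / (
        math.sqrt(2.0) * math.pi * molecular_diameter**2 * pressure)


def mach_disk_position(source: SourceConditions) -> float:
    """Axial Mach-disk location x_M = 0.67 d sqrt(P0/P1) from the capillary exit.

    Raises
    ------
    SubcriticalExpansionError
        If P0/P1 does not exceed the critical ratio, i.e. the expansion never
        becomes supersonic.
    """
    if source.pressure_ratio <= source.critical_ratio:
        raise SubcriticalExpansionError(
            "no supersonic expansion: P0/P1 = %.3g below critical ratio %.3g"
            % (source.pressure_ratio, source.critical_ratio))
    return 0.67 * source.capillary_diameter * math.sqrt(source.pressure_ratio)


# Ashkenas-Sherman far-field correlation constants for gamma = 1.4.
_AS_A = 3.65
_AS_Z0_OVER_D = 0.40
#: the centerline Mach number rises linearly from the stagnation limit (M=0)
#: at the exit plane to the Ashkenas-Sherman value one capillary diameter
#: downstream, where the far-field correlation takes over.
_BLEND_Z_OVER_D = 1.0


def _centerline_mach(z: np.ndarray, source: SourceConditions) -> np.ndarray:
    d = source.capillary_diameter
    g = source.gas.gamma
    zr = np.asarray(z, dtype=float) / d
    m_as = _AS_A * np.maximum(zr - _AS_Z0_OVER_D, 0.0) ** (g - 1.0)
    m_blend_top = _AS_A * (_BLEND_Z_OVER_D - _AS_Z0_OVER_D) ** (g - 1.0)
    m_near = m_blend_top * zr / _BLEND_Z_OVER_D
    return np.where(zr < _BLEND_Z_OVER_D, m_near, m_as)


def normal_shock_state(m1: float, gamma: float) -> tuple[float, float, float, float]:
    """Rankine-Hugoniot jumps across a normal shock.

    Returns (M2, T2/T1, p2/p1, rho2/rho1) for pre-shock Mach number ``m1``.
    """
    g = gamma
    m1sq = m1 * m1
    m2 = math.sqrt((1.0 + 0.5 * (g - 1.0) * m1sq) / (g * m1sq - 0.5 * (g - 1.0)))
    p_ratio = (2.0 * g * m1sq - (g - 1.0)) / (g + 1.0)
    t_ratio = ((2.0 * g * m1sq - (g - 1.0)) * ((g - 1.0) * m1sq + 2.0)) / (
        (g + 1.0) ** 2 * m1sq)
    rho_ratio = p_ratio / t_ratio
    return m2, t_ratio, p_ratio, rho_ratio


@dataclass(frozen=True)
class FlowField:
    """Axisymmetric analytic flow field with Mach-disk position.

    ``state(z, r)`` evaluates the local gas state; on the axis it reproduces
    :func:`centerline_state` exactly.  ``state_arrays`` is the vectorized form
    used by the ensemble transport integrators.
    """

    source: SourceConditions
    mach_disk_z: float
    z_max: float
    r_max: float
    spread_slope: float = 0.2          # half-width growth dw/dz
    resolution: int = 200
    _post: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.z_max <= 0 or self.r_max <= 0 or self.resolution <= 0:
            raise ValueError("flow-field grid must be positive")
        # Precompute the uniform post-shock state from the pre-shock
        # centerline Mach number at the Mach disk.
        src = self.source
        g = src.gas.gamma
        m1 = float(_centerline_mach(np.array([self.mach_disk_z]), src)[0])
        t1 = src.stagnation_temperature / (1.0 + 0.5 * (g - 1.0) * m1 * m1)
        p1 = src.stagnation_pressure * (t1 / src.stagnation_temperature) ** (
            g / (g - 1.0))
        m2, t_j, p_j, _ = normal_shock_state(m1, g)
        t2, p2 = t1 * t_j, p1 * p_j
        rho2 = p2 / (src.gas.specific_gas_constant * t2)
        u2 = m2 * math.sqrt(g * src.gas.specific_gas_constant * t2)
        object.__setattr__(self, "_post", {
            "M": m2, "T": t2, "p": p2, "rho": rho2, "u": u2})

    # -- scalar API ------------------------------------------------------
    def state(self, z: float, r: float = 0.0) -> GasState:
        arrs = self.state_arrays(np.array([z]), np.array([abs(r)]))
        return GasState(
            mach_number=float(arrs["M"][0]),
            temperature=float(arrs["T"][0]),
            density=float(arrs["rho"][0]),
            pressure=float(arrs["p"][0]),
            velocity=(float(arrs["u_z"][0]), float(arrs["u_r"][0])),
            mean_free_path=float(arrs["lam"][0]),
        )

    # -- vectorized API --------------------------------------------------
    def centerline_arrays(self, z: np.ndarray) -> dict:
        """Centerline (r = 0) state as arrays over axial positions ``z``."""
        src = self.source
        g = src.gas.gamma
        z = np.asarray(z, dtype=float)
        if np.any(z < 0):
            raise ValueError("axial position must be non-negative")
        rs = src.gas.specific_gas_constant
        m = _centerline_mach(z, src)
        t = src.stagnation_temperature / (1.0 + 0.5 * (g - 1.0) * m * m)
        p = src.stagnation_pressure * (t / src.stagnation_temperature) ** (
            g / (g - 1.0))
        u = m * np.sqrt(g * rs * t)
        post = self._post
        down = z >= self.mach_disk_z
        m = np.where(down, post["M"], m)
        t = np.where(down, post["T"], t)
        p = np.where(down, post["p"], p)
        u = np.where(down, post["u"], u)
        rho = p / (rs * t)
        return {"M": m, "T": t, "p": p, "rho": rho, "u": u}

    def half_width(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.source.capillary_diameter + self.spread_slope * np.asarray(z, dtype=float)

    def state_arrays(self, z: np.ndarray, r: np.ndarray) -> dict:
        """Vectorized off-axis state; symmetric in r."""
        src = self.source
        z = np.asarray(z, dtype=float)
        r = np.abs(np.asarray(r, dtype=float))
        c = self.centerline_arrays(z)
        w = self.half_width(z)
        gauss = np.exp(-0.5 * (r / w) ** 2)
        rs = src.gas.specific_gas_constant
        # Off axis the velocity decays on the Gaussian similarity profile and
        # the temperature follows total-enthalpy conservation, so the adiabatic
        # identity T (1 + (g-1)/2 M^2) = T0 holds at every evaluated point.
        t0 = src.stagnation_temperature
        p_bg = src.background_pressure
        u_z = c["u"] * gauss
        # Outward fanning: streamline angle grows with r on the spreading jet.
        u_r = u_z * self.spread_slope * np.clip(r / w, 0.0, 3.0)
        cp = src.gas.gamma * rs / (src.gas.gamma - 1.0)
        t = t0 - (u_z**2 + u_r**2) / (2.0 * cp)
        p = p_bg + (c["p"] - p_bg) * gauss
        rho = p / (rs * t)
        a = np.sqrt(src.gas.gamma * rs * t)
        m = np.hypot(u_z, u_r) / a
        lam = BOLTZMANN * t / (
            math.sqrt(2.0) * math.pi * src.gas.molecular_diameter**2 * p)
        return {"M": m, "T": t, "p": p, "rho": rho,
                "u_z": u_z, "u_r": u_r, "lam": lam}

    @property
    def post_shock(self) -> dict:
        """Uniform post-normal-shock centerline state (M, T, p, rho, u)."""
        return dict(self._post)

    # -- export ----------------------------------------------------------
    def centerline_table(self) -> "np.ndarray":
        z = np.linspace(0.0, self.z_max, self.resolution)
        c = self.centerline_arrays(z)
        return np.column_stack([z, c["M"], c["T"], c["p"], c["rho"], c["u"]])

    def to_json(self, path) -> None:
        table = self.centerline_table()
        payload = {
            "mach_disk_z": self.mach_disk_z,
            "columns": ["z", "M", "T", "p", "rho", "u"],
            "centerline": table.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def to_csv(self, path) -> None:
        table = self.centerline_table()
        np.savetxt(path, table, delimiter=",",
                   header="z,M,T,p,rho,u", comments="")


def centerline_state(z: float, source: SourceConditions,
                     field_: FlowField | None = None) -> GasState:
    """Gas state on the jet axis at axial position ``z`` (m)."""
    if z < 0:
        raise ValueError("axial position must be non-negative")
    if field_ is None:
        field_ = build_flow_field(source)
    return field_.state(z, 0.0)


def build_flow_field(source: SourceConditions,
                     grid: dict | None = None) -> FlowField:
    """Assemble the analytic flow field; ``grid`` takes z_max, r_max, resolution."""
    grid = dict(grid or {})
    z_max = grid.pop("z_max", 0.03)
    r_max = grid.pop("r_max", 0.01)
    resolution = grid.pop("resolution", 200)
    if grid:
        raise TypeError(f"unknown grid keys: {sorted(grid)}")
    return FlowField(source=source,
                     mach_disk_z=mach_disk_position(source),
                     z_max=z_max, r_max=r_max, resolution=resolution)
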