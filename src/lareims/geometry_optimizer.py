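"""End-to-end interface optimization: sweep surface shape, position, temperature.

Each sweep cell launches the same seeded droplet population (common random
numbers across cells for variance reduction), transports it through the free
jet, detects impacts on the collision surface, converts impacts to secondary
ions with the declustering yield, traces the ions out of the surface region
and through the ion guide, and records the end-to-end efficiency

    end_to_end = captured ions / launched droplets
               = impact_fraction x mean yield x escape x capture

with the attribution factors logged per cell so the optimum's mechanism is
inspectable.  Optimization itself is an exhaustive grid argmax.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .config import SimulationConfig, default_config
from .impact_declustering import (CollisionSurface, declustering_yield,
                                  surface_normal)
from .ion_capture import (IonGuide, capture_efficiency, trace_ions_guide,
                          trace_surface_escape, uniform_background)
from .jet_flow import build_flow_field, mean_free_path
from .particle_transport import advance_ensemble
from .synthetic_data import gen_aerosol

__all__ = ["SweepSpec", "EfficiencyMap", "CellResult", "run_sweep",
           "find_optimum", "simulate_cell"]

_SHAPE_ORDER = {"sphere": 0, "plane": 1, "cone": 2}


@dataclass(frozen=True)
class SweepSpec:
    """Grid of interface configurations to evaluate."""

    shapes: tuple = ("sphere", "plane")
    z_grid: tuple = (2e-3, 4e-3, 5e-3, 6e-3, 7e-3, 9e-3, 12e-3)   # m
    temperature_grid: tuple = (400.0, 600.0, 800.0, 1000.0, 1200.0, 1500.0)  # K
    n_droplets: int = 2000
    seed: int = 17

    def __post_init__(self) -> None:
        if not self.shapes or not self.z_grid or not self.temperature_grid:
            raise ValueError("sweep grids must be non-empty")
        if self.n_droplets < 1:
            raise ValueError("need at least one droplet per cell")
        unknown = set(self.shapes) - set(_SHAPE_ORDER)
        if unknown:
            raise ValueError(f"unknown shapes {sorted(unknown)}")


@dataclass
class CellResult:
    shape: str
    z_s: float
    temperature: float
    end_to_end_efficiency: float
    impact_fraction: float
    mean_impact_speed: float
    mean_yield: float
    escape_fraction: float
    capture_fraction: float
    ci95: tuple
    n_droplets: int
    error: str | None = None


@dataclass
class EfficiencyMap:
    """Sweep results keyed by (shape, z_s, T_s)."""

    cells: dict
    mach_disk_z: float
    spec: SweepSpec

    def __len__(self) -> int:
        return len(self.cells)

    def to_records(self) -> list[dict]:
        return [vars(c).copy() for c in self.cells.values()]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.to_records())

    def to_json(self, path) -> None:
        payload = {"mach_disk_z": self.mach_disk_z,
                   "cells": self.to_records()}
        with open(path, "w") as fh:
            json.dump(payload, fh, default=lambda o: list(o))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot_heatmap(self, path, shape: str = "sphere") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        zs = sorted({k[1] for k in self.cells if k[0] == shape})
        ts = sorted({k[2] for k in self.cells if k[0] == shape})
        img = np.full((len(ts), len(zs)), np.nan)
        for (sh, z, t), cell in self.cells.items():
            if sh == shape:
                img[ts.index(t), zs.index(z)] = cell.end_to_end_efficiency
        fig, ax = plt.subplots(figsize=(6, 4))
        dz = (zs[1] - zs[0]) if len(zs) > 1 else 1e-3
        dt_ = (ts[1] - ts[0]) if len(ts) > 1 else 100.0
        im = ax.imshow(img, origin="lower", aspect="auto",
                       extent=[(min(zs) - dz / 2) * 1e3,
                               (max(zs) + dz / 2) * 1e3,
                               min(ts) - dt_ / 2, max(ts) + dt_ / 2])
        ax.axvline(self.mach_disk_z * 1e3, color="w", ls="--", lw=1)
        ax.set_xlabel("surface position z_s (mm)")
        ax.set_ylabel("surface temperature T_s (K)")
        ax.set_title(f"end-to-end efficiency ({shape})")
        fig.colorbar(im, ax=ax, label="captured / launched")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _local_jet_state(flow, z_s: float) -> dict:
    """Unperturbed free-stream state at the surface position.

    Upstream of the Mach disk this is the cold, rarefied supersonic state;
    downstream it is the uniform post-shock drift.
    """
    gas = flow.source.gas
    if z_s >= flow.mach_disk_z:
        post = flow.post_shock
        lam = mean_free_path(post["p"], post["T"], gas.molecular_diameter)
        return {"u": post["u"], "T": post["T"], "rho": post["rho"],
                "p": post["p"], "lam": lam}
    c = flow.centerline_arrays(np.array([z_s]))
    lam = mean_free_path(float(c["p"][0]), float(c["T"][0]),
                         gas.molecular_diameter)
    return {"u": float(c["u"][0]), "T": float(c["T"][0]),
            "rho": float(c["rho"][0]), "p": float(c["p"][0]), "lam": lam}


def _droplet_phase(shape: str, z_s: float, spec: SweepSpec,
                   config: SimulationConfig, flow) -> dict:
    """Transport the common droplet population to one surface placement.

    Independent of surface temperature, so sweeps share it across the T grid.
    """
    surface = CollisionSurface(
        shape=shape, characteristic_radius=config.surface_radii[shape],
        axial_position=z_s, temperature=300.0)
    aerosol = replace(config.aerosol, n=spec.n_droplets, seed=spec.seed)
    droplets = gen_aerosol(aerosol, flow)
    res = advance_ensemble(droplets, flow, surface=surface,
                           seed=spec.seed + 1, t_max=config.droplet_t_max)
    return {"n": len(droplets), "result": res}


def simulate_cell(shape: str, z_s: float, temperature: float,
                  spec: SweepSpec, config: SimulationConfig,
                  flow=None, _droplets: dict | None = None) -> CellResult:
    """Full droplet -> impact -> yield -> escape -> capture chain for one cell."""
    if flow is None:
        flow = build_flow_field(config.source)
    surface = CollisionSurface(
        shape=shape, characteristic_radius=config.surface_radii[shape],
        axial_position=z_s, temperature=temperature)
    if _droplets is None:
        _droplets = _droplet_phase(shape, z_s, spec, config, flow)
    n = _droplets["n"]
    res = _droplets["result"]
    hit = res["fate"] == "impacted_surface"
    n_hit = int(hit.sum())
    if n_hit == 0:
        ci = capture_efficiency(["lost"] * n).ci95
        return CellResult(shape, z_s, temperature, 0.0, 0.0, float("nan"),
                          0.0, 0.0, 0.0, ci, n)
    speeds = res["impact_speed"][hit]
    points = res["impact_point"][hit]
    yields = declustering_yield(config.declustering, temperature, speeds)
    rng = np.random.default_rng(spec.seed + 2)
    emitted = rng.random(n_hit) < yields
    n_emit = int(emitted.sum())
    mean_yield = float(yields.mean())
    impact_fraction = n_hit / n
    mean_speed = float(speeds.mean())
    if n_emit == 0:
        ci = capture_efficiency(["lost"] * n).ci95
        return CellResult(shape, z_s, temperature, 0.0, impact_fraction,
                          mean_speed, mean_yield, 0.0, 0.0, ci, n)
    normals = surface_normal(points[emitted], surface)
    local = _local_jet_state(flow, z_s)
    esc = trace_surface_escape(points[emitted], normals, surface, local,
                               config.ion_spec, None,
                               model=config.surface_region,
                               seed=spec.seed + 3, gas=config.source.gas)
    n_escaped = len(esc["position"])
    if n_escaped == 0:
        ci = capture_efficiency(["lost"] * n).ci95
        return CellResult(shape, z_s, temperature, 0.0, impact_fraction,
                          mean_speed, mean_yield, 0.0, 0.0, ci, n)
    entrance = (surface.axial_position + 2e-4 if shape == "plane"
                else surface.center_z + surface.characteristic_radius)
    guide = IonGuide(
        entrance_z=entrance, exit_z=entrance + config.guide_length,
        inner_radius=config.guide_inner_radius,
        axial_field=config.guide_axial_field,
        pseudopotential_depth=config.guide_pseudopotential,
        background=uniform_background(config.guide_pressure,
                                      config.guide_temperature,
                                      config.source.gas),
        gas=config.source.gas)
    ion = config.ion_spec
    n_i = n_escaped
    fates = trace_ions_guide(
        esc["position"], esc["velocity"], np.full(n_i, ion.mass),
        np.full(n_i, ion.charge), np.full(n_i, ion.diameter),
        np.full(n_i, ion.material_density), guide, seed=spec.seed + 4,
        t_max=config.guide_t_max)
    n_cap = int(np.sum(fates == "captured"))
    summary = capture_efficiency(
        ["captured"] * n_cap + ["lost"] * (n - n_cap))
    return CellResult(shape, z_s, temperature,
                      end_to_end_efficiency=n_cap / n,
                      impact_fraction=impact_fraction,
                      mean_impact_speed=mean_speed, mean_yield=mean_yield,
                      escape_fraction=n_escaped / n_emit,
                      capture_fraction=n_cap / n_escaped,
                      ci95=summary.ci95, n_droplets=n)


def run_sweep(spec: SweepSpec, config: SimulationConfig | None = None,
              physics=None) -> EfficiencyMap:
    """Evaluate every sweep cell; per-cell errors are recorded, not fatal.

    ``physics`` may replace the per-cell simulation with any callable
    ``(shape, z_s, T_s, spec, config) -> CellResult`` (used for analytic
    stub checks); the default is :func:`simulate_cell`.
    """
    config = config or default_config()
    flow = build_flow_field(config.source)
    cells = {}
    for shape in spec.shapes:
        for z_s in spec.z_grid:
            droplets = None
            for t_s in spec.temperature_grid:
                key = (shape, float(z_s), float(t_s))
                try:
                    if physics is not None:
                        cells[key] = physics(shape, float(z_s), float(t_s),
                                             spec, config)
                    else:
                        if droplets is None:
                            droplets = _droplet_phase(shape, float(z_s),
                                                      spec, config, flow)
                        cells[key] = simulate_cell(shape, float(z_s),
                                                   float(t_s), spec, config,
                                                   flow=flow,
                                                   _droplets=droplets)
                except Exception as exc:  # recorded per cell
                    cells[key] = CellResult(shape, float(z_s), float(t_s),
                                            float("nan"), float("nan"),
                                            float("nan"), float("nan"),
                                            float("nan"), float("nan"),
                                            (float("nan"), float("nan")),
                                            spec.n_droplets, error=str(exc))
    return EfficiencyMap(cells=cells, mach_disk_z=flow.mach_disk_z, spec=spec)


def find_optimum(emap: EfficiencyMap) -> CellResult:
    """Argmax of end-to-end efficiency.

    Ties break toward smaller z_s, then lower T_s, then shape order
    sphere < plane < cone.
    """
    valid = [c for c in emap.cells.values()
             if c.error is None and math.isfinite(c.end_to_end_efficiency)]
    if not valid:
        raise ValueError("efficiency map is empty")
    return min(valid, key=lambda c: (-c.end_to_end_efficiency, c.z_s,
                                     c.temperature, _SHAPE_ORDER[c.shape]))
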