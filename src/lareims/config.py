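"""Bundled simulator configuration with YAML round trip.

All constants the simulation wing depends on live here: the gas source, the
aerosol population, the declustering yield model, the secondary-ion spec,
the guide abstraction and the near-surface escape model.  Every value is a
declared, calibrated default -- none is a measured instrument parameter.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .impact_declustering import DeclusteringModel, SecondaryIonSpec
from .ion_capture import SurfaceRegionModel
from .jet_flow import Gas, NITROGEN, SourceConditions
from .synthetic_data import AerosolSpec

__all__ = ["SimulationConfig", "default_config", "load_config", "save_config"]


@dataclass(frozen=True)
class SimulationConfig:
    source: SourceConditions = field(default_factory=SourceConditions)
    aerosol: AerosolSpec = field(default_factory=AerosolSpec)
    declustering: DeclusteringModel = field(default_factory=DeclusteringModel)
    ion_spec: SecondaryIonSpec = field(default_factory=SecondaryIonSpec)
    surface_region: SurfaceRegionModel = field(default_factory=SurfaceRegionModel)
    surface_radii: dict = field(default_factory=lambda: {
        "sphere": 1.5e-3, "plane": 3.0e-3, "cone": 1.5e-3})
    guide_length: float = 10.0e-3        # m
    guide_inner_radius: float = 2.5e-3   # m
    guide_axial_field: float = 3000.0    # V/m
    guide_pseudopotential: float = 2.0   # V
    guide_pressure: float = 100.0        # Pa
    guide_temperature: float = 300.0     # K
    droplet_t_max: float = 1.0e-4        # s
    guide_t_max: float = 1.0e-3          # s


def default_config() -> SimulationConfig:
    return SimulationConfig()


def _as_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["source"]["gas"] = asdict(cfg.source.gas)
    return d


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    src = dict(raw.pop("source", {}))
    gas = Gas(**src.pop("gas")) if "gas" in src else NITROGEN
    return SimulationConfig(
        source=SourceConditions(gas=gas, **src),
        aerosol=AerosolSpec(**raw.pop("aerosol", {})),
        declustering=DeclusteringModel(**raw.pop("declustering", {})),
        ion_spec=SecondaryIonSpec(**raw.pop("ion_spec", {})),
        surface_region=SurfaceRegionModel(**raw.pop("surface_region", {})),
        **raw)
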