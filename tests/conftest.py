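import math

import numpy as np
import pytest

from lareims.jet_flow import NITROGEN, SourceConditions, build_flow_field


class UniformField:
    """Minimal flow-field stand-in: constant velocity, quiescent-gas state.

    Mimics the FlowField query interface so transport can be exercised
    against closed-form solutions (uniform flow, zero flow).
    """

    def __init__(self, u_z=0.0, temperature=300.0, pressure=101325.0,
                 z_max=1.0, r_max=1.0, gas=NITROGEN):
        self.u_z = u_z
        self.temperature = temperature
        self.pressure = pressure
        self.z_max = z_max
        self.r_max = r_max
        self.mach_disk_z = z_max

        class _Src:
            pass

        self.source = _Src()
        self.source.gas = gas

    def state_arrays(self, z, r):
        z = np.asarray(z, dtype=float)
        lam = 1.380649e-23 * self.temperature / (
            math.sqrt(2) * math.pi
            * self.source.gas.molecular_diameter**2 * self.pressure)
        shape = np.broadcast(z, np.asarray(r)).shape
        return {
            "u_z": np.full(shape, self.u_z),
            "u_r": np.zeros(shape),
            "T": np.full(shape, self.temperature),
            "p": np.full(shape, self.pressure),
            "rho": np.full(shape, self.pressure / (
                self.source.gas.specific_gas_constant * self.temperature)),
            "lam": np.full(shape, lam),
            "M": np.zeros(shape),
        }


@pytest.fixture
def uniform_field():
    return UniformField


@pytest.fixture(scope="session")
def source():
    return SourceConditions()


@pytest.fixture(scope="session")
def flow(source):
    return build_flow_field(source)


@pytest.fixture(scope="session")
def phantom_truth():
    from lareims.synthetic_data import gen_phantom

    return gen_phantom(rows=24, cols=24, layout="stripes", seed=17)


@pytest.fixture(scope="session")
def phantom_grid(phantom_truth):
    """Laser-modality phantom run through the full preprocessing pipeline."""
    from lareims.msi_pipeline import reconstruct_image
    from lareims.synthetic_data import gen_msi_dataset

    stream, info = gen_msi_dataset(phantom_truth, modality="laser")
    return reconstruct_image(stream), info


@pytest.fixture(scope="session")
def phantom_features(phantom_grid):
    from lareims.synthetic_data import feature_matrix_from_grid

    grid, info = phantom_grid
    return feature_matrix_from_grid(grid, info["labels"], modality="laser")


@pytest.fixture(scope="session")
def default_sweep_map():
    """The shipped-defaults geometry sweep (seed 17, 2000 droplets/cell).

    Session-scoped: this is the expensive simulation shared by the sweep
    property tests.
    """
    from lareims.config import default_config
    from lareims.geometry_optimizer import SweepSpec, run_sweep

    return run_sweep(SweepSpec(n_droplets=2000, seed=17), default_config())
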