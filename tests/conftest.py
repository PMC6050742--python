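import numpy as np
import pytest

from osteonflow import (
    Loading,
    MaterialConstants,
    compute_stiffness,
)
from osteonflow.scenarios import CORTICAL_BONE, reference_stack


@pytest.fixture(scope="session")
def bone() -> MaterialConstants:
    """Cortical-bone poroelastic constants used throughout."""
    return CORTICAL_BONE


@pytest.fixture(scope="session")
def stiff(bone):
    return compute_stiffness(bone)


@pytest.fixture(scope="session")
def loading() -> Loading:
    """Benchmark loading: strain amplitude 0.00092 at omega = 21 rad/s."""
    return Loading(eps_z0=0.00092, omega=21.0)


@pytest.fixture(scope="session")
def case1_stack():
    return reference_stack("case1")


@pytest.fixture(scope="session")
def uniform_stack():
    return reference_stack("uniform")


@pytest.fixture
def config_tree() -> dict:
    """A complete, valid configuration tree (micrometre / rad-s units)."""
    return {
        "material": {
            "E_r_GPa": 15.9, "E_z_GPa": 20.3, "nu_r": 0.328, "nu_z": 0.25,
            "alpha": 0.132, "alpha_prime": 0.092, "N_GPa": 38.0, "mu_Pa_s": 1e-3,
        },
        "geometry": {"a_um": 50.0, "b_um": 150.0, "n_layers": 6},
        "loading": {"eps_z0": 0.00092, "omega_rad_s": 21.0},
        "layers": {"k_m2": [0.5e-18, 0.7e-18, 0.9e-18, 1.1e-18, 1.3e-18, 1.5e-18]},
    }


def rel_l2(x: np.ndarray, ref: np.ndarray) -> float:
    return float(
        np.sqrt(np.mean(np.abs(x - ref) ** 2)) / np.sqrt(np.mean(np.abs(ref) ** 2))
    )
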