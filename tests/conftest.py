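import numpy as np
import pytest

from aggkit.kinetics import KineticParameters
from aggkit.synth import SyntheticSpec, default_parameters, generate_tht_dataset


@pytest.fixture(scope="session")
def default_params() -> KineticParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced plate (5 concentrations, 3 replicates, coarse grid) for fast tests."""
    return SyntheticSpec(
        seed=11,
        concentrations=(1.0, 2.0, 3.0, 5.0, 8.0),
        n_replicates=3,
        t_grid=np.linspace(0.0, 24.0, 481),
    )


@pytest.fixture(scope="session")
def small_plate(small_spec):
    """(traces, metadata, ground_truth) of the reduced plate."""
    return generate_tht_dataset(small_spec)
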