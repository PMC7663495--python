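import numpy as np
import pytest

from slipgait import cli_io, slip3d
from slipgait.synthetic_cohort import CohortConfig, generate_cohort, sample_subject


@pytest.fixture(scope="session")
def nominal_params():
    """Nominal 60 kg walker at 1.3 m/s."""
    return slip3d.default_parameters(speed=1.3)


@pytest.fixture(scope="session")
def nominal_gait(nominal_params):
    return slip3d.find_periodic_gait(nominal_params, 1.3)


@pytest.fixture(scope="session")
def nominal_trajectory(nominal_params, nominal_gait):
    return slip3d.simulate_stride(
        nominal_params, nominal_gait, n_strides=3, sample_rate=1000.0
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small single-speed cohort for IO/format and counting tests."""
    cfg = CohortConfig(n_subjects=5, speeds=(1.3,), strides_per_speed=3, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The stated-world evaluation cohort: 8 subjects x 4 speeds x 10 stances."""
    return generate_cohort(CohortConfig(n_subjects=8, seed=0))


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    return cli_io.build_dataset(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_subject():
    return sample_subject(np.random.default_rng(5), "T0")
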