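import numpy as np
import pytest

from lamsurf.drain import LeakageModel
from lamsurf.phantom import AcquisitionModel, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced lattice for fast end-to-end style tests."""
    return PhantomSpec(
        ecc_levels_deg=(1.5, 2.5, 3.75),
        n_angles=2,
        n_compartments=4,
        conditions=("motion", "dynamic"),
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)


@pytest.fixture
def quiet_acquisition():
    """Noise-free acquisition for exact-recovery checks."""
    return AcquisitionModel(noise_sd_pct=0.0, drift_amp_pct=0.0, subject_sd=0.0)


@pytest.fixture
def leakage10():
    return LeakageModel.uniform(10, 0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
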