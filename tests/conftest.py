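import numpy as np
import pytest

from ifcmrd.core import AcquisitionMode
from ifcmrd.synthetic import default_phenotypes, generate_sample


@pytest.fixture(scope="session")
def phenotypes():
    return default_phenotypes()


@pytest.fixture(scope="session")
def stained_mode():
    return AcquisitionMode(stained=True, laser_on=True)


@pytest.fixture(scope="session")
def mixed_sample(stained_mode):
    """One 2,000-cell stained sample with 10% contaminants (shared:
    generation is the expensive part of most QC/gating checks)."""
    rng = np.random.default_rng(20240917)
    return generate_sample(
        "PX", "pres", 2000, (1 / 3, 1 / 3, 1 / 3),
        {"clump": 0.05, "out_of_focus": 0.05}, stained_mode, rng,
    )


@pytest.fixture(scope="session")
def small_sample(stained_mode):
    """A 60-cell clean sample for cheap structural tests."""
    rng = np.random.default_rng(7)
    return generate_sample(
        "PS", "pres", 60, (0.4, 0.3, 0.3), {}, stained_mode, rng
    )
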