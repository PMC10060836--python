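import numpy as np
import pytest

from awfc import ROIAtlas, ROI, SimConfig, default_atlas, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_atlas():
    """Three ROIs in two networks — fast fixture for plumbing tests."""
    return ROIAtlas(
        [
            ROI(1, "N1", "alpha", "A", (0, 0, 0), 4),
            ROI(2, "N1", "beta", "B", (3, 4, 0), 3),
            ROI(3, "N2", "gamma", "C", (0, 0, 10), 5),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-size synthetic cohort shared across read-only tests."""
    return generate_cohort(SimConfig(seed=7))
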