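import numpy as np
import pytest

from crossconn import SyntheticConfig, generate_twin_cohorts
from crossconn.spectral import AnalyticSignal, band_by_name


@pytest.fixture(scope="session")
def alpha():
    return band_by_name("alpha")


def make_analytic(values, fs=200.0, band=None):
    """Wrap a complex array as an AnalyticSignal without filtering."""
    return AnalyticSignal(band=band or band_by_name("alpha"),
                          sampling_rate=fs,
                          values=np.asarray(values, dtype=complex))


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled twin-cohort configuration for fast unit tests."""
    return SyntheticConfig(
        n_rois=6, n_subjects_reference=5, n_subjects_test=3,
        rois_per_reference_subject=3, channels_per_roi=1,
        n_couplings=5, duration=30.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return generate_twin_cohorts(small_config)
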