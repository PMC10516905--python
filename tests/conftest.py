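import numpy as np
import pytest

from cardioresp import synth
from cardioresp.features import feature_table


@pytest.fixture(scope="session")
def rest_profile():
    return synth.DEFAULT_PROFILES["Rest"]


@pytest.fixture(scope="session")
def sict_profile():
    return synth.DEFAULT_PROFILES["SICT"]


@pytest.fixture(scope="session")
def quiet_profile():
    """Low-noise profile for detection ground-truth tests."""
    return synth.ConditionProfile(
        name="quiet", mean_rr=850.0, lf_depth=25.0, hf_depth=30.0,
        rr_noise_sd=15.0, hr_entropy_mix=0.7, resp_rate=15.0,
        resp_amp=100.0, ie_ratio=0.8, bb_jitter_sd=250.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject events-only cohort with the default condition profiles."""
    cfg = synth.CohortConfig(n_subjects=6, duration=720.0, master_seed=11)
    return synth.generate_cohort(cfg, waveforms=False)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table, exclusions = feature_table(small_cohort, path="truth")
    assert not exclusions
    return table


@pytest.fixture(scope="session")
def cohort_table():
    """Full 26-subject feature table (truth path, default profiles)."""
    cfg = synth.CohortConfig(master_seed=0)
    recs = synth.generate_cohort(cfg, waveforms=False)
    table, exclusions = feature_table(recs, path="truth")
    assert not exclusions
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
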