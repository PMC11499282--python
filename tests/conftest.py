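import warnings

import numpy as np
import pytest

from pedgait.records import SubjectProfile
from pedgait.synth import SimConfig, simulate_free_living_days, simulate_walk_pass

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile(subject_id="S001", age_years=8.0, height_m=1.30)


@pytest.fixture(scope="session")
def clean_pass(profile):
    """Noise-free 30 s natural pass at 110 spm: 55 planted ICs."""
    cfg = SimConfig(noise_sd_g=0.0, seed=1)
    rec, truth = simulate_walk_pass(profile, "natural", 30.0, cfg, cadence_spm=110.0)
    return rec, truth


@pytest.fixture(scope="session")
def free_living_day(profile):
    """One simulated lumbar day shared across bout/wear tests."""
    cfg = SimConfig(seed=3)
    return simulate_free_living_days(profile, 1, cfg, site="lumbar")


def rng(seed=0):
    return np.random.default_rng(seed)
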