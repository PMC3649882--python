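import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppghemo.synthetic import SynthCohortConfig, SynthPPGConfig, generate_cohort, generate_ppg

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_recording():
    """60 s of clean 60-bpm PPG: one pulse per second, no modulation or noise."""
    cfg = SynthPPGConfig(
        duration_s=60.0, fs=200.0, heart_rate_bpm=60.0, pulse_width_frac=0.3,
        am_components=(), baseline_components=(), noise_sd=0.0, seed=0,
    )
    return generate_ppg(cfg)


@pytest.fixture(scope="session")
def modulated_recording():
    """10-min 84-bpm PPG with a single 0.1 Hz amplitude modulation, depth 0.2."""
    cfg = SynthPPGConfig(
        duration_s=600.0, fs=200.0, heart_rate_bpm=84.0, pulse_width_frac=0.3,
        am_components=((0.10, 0.2),), baseline_components=(), noise_sd=0.0, seed=0,
    )
    return generate_ppg(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 48-subject cohort with the planted CO model."""
    return generate_cohort(SynthCohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
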