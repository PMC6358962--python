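import numpy as np
import pytest

from ppgpain import synth
from ppgpain.pipeline import PipelineConfig, cohort_features


@pytest.fixture(scope="session")
def clean_config():
    """Constant 60-bpm, noise-free, modulation-free 300-s record config."""
    return synth.SynthConfig(
        duration_s=300.0, mean_hr_bpm=60.0, modulations=(),
        baseline_amp=0.0, noise_sd=0.0, ectopic_rate_per_min=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return synth.generate_record(clean_config)


@pytest.fixture(scope="session")
def modulated_record():
    """Realistic 14-min record: HRV modulation, wander, mild noise."""
    return synth.generate_record(synth.SynthConfig(seed=21))


@pytest.fixture(scope="session")
def small_cohort():
    """8-subject paired cohort with default class-conditional parameters."""
    return synth.generate_cohort(8, seed=11)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    matrix = cohort_features(small_cohort, PipelineConfig())
    assert len(matrix) > 0
    return matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
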