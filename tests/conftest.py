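import numpy as np
import pytest

from neostress import CohortSpec, EffectSpec, PipelineConfig, Tachogram, UniformSeries


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def flat_tachogram():
    """20 min of constant 0.5 s RR."""
    rr = np.full(2400, 0.5)
    return Tachogram.from_rr(rr)


@pytest.fixture
def flat_spo2():
    return UniformSeries(np.full(1200, 96.0), rate=1.0)


@pytest.fixture
def small_cohort_spec():
    return CohortSpec(n_subjects_per_group=4, record_duration_s=1200.0,
                      events_per_subject_mean=2.0, eeg_rate_hz=64.0)


@pytest.fixture
def default_effects():
    return EffectSpec()


def random_tachogram(rng, n_beats=1500, base=0.45, n_excursions=3):
    """Random tachogram with occasional supra-threshold excursions."""
    rr = base * (1.0 + 0.05 * rng.standard_normal(n_beats))
    for _ in range(n_excursions):
        start = rng.integers(50, n_beats - 60)
        length = rng.integers(2, 25)
        rr[start:start + length] *= rng.uniform(1.2, 2.4)
    return Tachogram.from_rr(np.clip(rr, 0.25, 1.9))
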