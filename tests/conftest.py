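import numpy as np
import pytest

from cbcsig import scoring, startle, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One default cohort (19 control / 20 stress), shared across tests."""
    cfg = synthetic.CohortConfig(seed=11)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_default_cohort(default_cohort):
    thresholds, scores, labels = scoring.score_cohort(
        default_cohort.measurements, default_cohort.config.metric_registry
    )
    return default_cohort, thresholds, scores, labels


@pytest.fixture
def samples_3v3():
    return [(f"L{i}", "stress_low") for i in range(3)] + [
        (f"H{i}", "stress_high") for i in range(3)
    ]


@pytest.fixture
def samples_5c_3v3(samples_3v3):
    return [(f"C{i}", "control") for i in range(5)] + samples_3v3


def make_flat_trace(level=2.0, sampling_rate=100.0, duration=10.0, stimuli=((5.0, 110.0),)):
    n = int(duration * sampling_rate)
    return startle.ActivityTrace(
        sampling_rate, np.full(n, float(level)), list(stimuli)
    )
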