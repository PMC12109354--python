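import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dtw100 import Modality, RunConfig, SignalTrace
from dtw100.preprocess import build_reference, preprocess_and_average, preprocess_trials
from dtw100.stats_report import StudySample
from dtw100.synthetic_data import CohortSpec, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tone(freq, rate=2000.0, seconds=4.0, amp=1.0, modality=Modality.LFP, phase=0.0):
    t = np.arange(int(round(seconds * rate))) / rate
    return SignalTrace(amp * np.sin(2 * np.pi * freq * t + phase), rate=rate, modality=modality)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale analysis config: 1 s epochs at 500 Hz."""
    return RunConfig(rate=500.0, epoch_seconds=1.0, baseline_window_seconds=0.5)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """Tiny preprocessed synthetic study: reference pair + pre/post samples."""
    common = dict(n_trials=5, rate=500.0, epoch_seconds=1.0, seed=11)
    normal = generate_cohort(CohortSpec("normal", n_subjects=3, **common))
    pre = generate_cohort(CohortSpec("bcao_pre", n_subjects=2, **common))
    post = generate_cohort(CohortSpec("bcao_post", n_subjects=2, **common))
    reference = build_reference(
        [preprocess_trials(l, small_cfg) for l, _ in normal],
        [preprocess_trials(e, small_cfg) for _, e in normal],
    )
    samples = [
        StudySample(
            sample_id=f"s{i}",
            phase=phase,
            lfp=preprocess_and_average(l, small_cfg),
            emg=preprocess_and_average(e, small_cfg),
        )
        for phase, cohort in (("pre", pre), ("post", post))
        for i, (l, e) in enumerate(cohort)
    ]
    return reference, samples
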