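import numpy as np
import pytest

from gestwear.har import ClassifierSpec, SplitProtocol, train_classifier
from gestwear.io import AccelerometerRecording
from gestwear.synthetic import (
    ActivityScheduleEntry,
    SignalModelParams,
    generate_har_training_set,
    synthesize_signal,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(time_s, acc=None, fs=20.0, patient_id="T", study_span_h=None):
    time_s = np.asarray(time_s, dtype=float)
    if acc is None:
        acc = np.tile([0.0, 0.0, 1.0], (time_s.size, 1))
    return AccelerometerRecording(patient_id, fs, time_s, np.asarray(acc, float), study_span_h)


@pytest.fixture
def sitting_with_bursts():
    """One hour of sitting with planted gesture bursts and ground truth."""
    params = SignalModelParams(gesture_rate_per_h=30.0)
    sched = [ActivityScheduleEntry("sitting", 0.0, 3600.0)]
    rec, truth = synthesize_signal(sched, params, seed=42)
    return sched, rec, truth, params


@pytest.fixture(scope="session")
def small_har_setup():
    """A compact trained HAR model shared across tests (4 subjects/source)."""
    windowsets, sources = generate_har_training_set(n_per_source=4, minutes=10.0, seed=7)
    split = SplitProtocol.leave_one_out_per_source(sources, seed=3)
    model, report = train_classifier(windowsets, ClassifierSpec(seed=0), split)
    return windowsets, sources, split, model, report
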