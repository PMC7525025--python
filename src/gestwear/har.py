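"""Human activity recognition on fixed-length windows of wrist acceleration.

The classifier assigns each window one of eight fine activity states which
collapse onto the ambulatory/stationary dichotomy (gait-involving vs
non-locomotive).  The supported backend is a handcrafted-feature baseline:
per-axis and magnitude summary statistics plus 0.5-5 Hz spectral features,
standardised and fed to a multinomial logistic regression.  Evaluation
follows a subject-wise protocol: one held-out subject per source for
validation and one for testing, the rest train.

Per-sample labels are bridged from window labels by majority vote across
the windows covering a sample, with the earliest window breaking ties —
gesture detection downstream needs sample-resolution stationarity.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import states
from .errors import ConfigError, ProtocolError
from .io import AccelerometerRecording

FEATURE_CHANNELS = ("ax", "ay", "az", "mag")
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in FEATURE_CHANNELS for stat in ("mean", "sd", "domfreq_hz", "bandpower")
) + ("corr_xy", "corr_xz", "corr_yz")

BAND_HZ = (0.5, 5.0)


@dataclasses.dataclass
class WindowSet:
    """Fixed-duration analysis windows over one recording.

    Windows tile the covered spans on a stride grid anchored at the first
    sample; windows covering less than ``min_coverage`` of their nominal
    sample count are dropped.  ``true_fine`` holds majority ground-truth
    fine-state codes when annotations were supplied (-1 otherwise).
    """

    rec: AccelerometerRecording
    duration_s: float
    stride_s: float
    min_coverage: float
    start_s: np.ndarray          # (n,)
    idx: np.ndarray              # (n, 2) half-open sample-index bounds
    coverage: np.ndarray         # (n,)
    true_fine: np.ndarray        # (n,) int8 codes, -1 = unknown

    def __len__(self) -> int:
        return int(self.start_s.size)

    @property
    def patient_id(self) -> str:
        return self.rec.patient_id

    def features(self) -> np.ndarray:
        """Feature matrix, one row per window (see ``FEATURE_NAMES``)."""
        return _extract_features(self)


def window_signal(
    rec: AccelerometerRecording,
    duration_s: float = 5.0,
    stride_s: float = 5.0,
    annotations=None,
    min_coverage: float = 0.8,
) -> WindowSet:
    """Tile the recording into windows; drop under-covered ones."""
    if duration_s <= 0 or stride_s <= 0:
        raise ConfigError("duration_s and stride_s must be positive")
    t = rec.time_s
    if t.size == 0:
        empty = np.empty(0)
        return WindowSet(rec, duration_s, stride_s, min_coverage, empty,
                         np.empty((0, 2), int), empty, np.empty(0, np.int8))
    t0 = t[0]
    end = t[-1] + rec.period_s
    n_pos = int(np.floor((end - t0 - duration_s) / stride_s + 1e-9)) + 1
    if n_pos <= 0:
        empty = np.empty(0)
        return WindowSet(rec, duration_s, stride_s, min_coverage, empty,
                         np.empty((0, 2), int), empty, np.empty(0, np.int8))
    pos = t0 + stride_s * np.arange(n_pos)
    i0 = np.searchsorted(t, pos - 1e-9, side="left")
    i1 = np.searchsorted(t, pos + duration_s - 1e-9, side="left")
    expected = duration_s * rec.sample_rate_hz
    coverage = (i1 - i0) / expected
    keep = coverage >= min_coverage
    pos, i0, i1, coverage = pos[keep], i0[keep], i1[keep], coverage[keep]

    fine = np.full(pos.size, -1, dtype=np.int8)
    if annotations is not None:
        from .synthetic import schedule_sample_labels

        sample_fine, _ = schedule_sample_labels(annotations, t)
        for k in range(pos.size):
            lab = sample_fine[i0[k]:i1[k]]
            lab = lab[lab >= 0]
            if lab.size:
                fine[k] = np.bincount(lab).argmax()
    return WindowSet(
        rec, duration_s, stride_s, min_coverage, pos,
        np.column_stack([i0, i1]).astype(np.int64), coverage, fine,
    )


def _features_for_length(X: np.ndarray, fs: float) -> np.ndarray:
    """Vectorised features for a batch of equal-length windows (n, w, 3)."""
    n, w, _ = X.shape
    mag = np.linalg.norm(X, axis=2)
    chans = np.concatenate([X, mag[:, :, None]], axis=2)  # (n, w, 4)
    mean = chans.mean(axis=1)
    sd = chans.std(axis=1)
    centered = chans - mean[:, None, :]
    F = np.fft.rfft(centered, axis=1)
    P = (np.abs(F) ** 2) * (2.0 / w**2)
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    band = (freqs >= BAND_HZ[0]) & (freqs <= BAND_HZ[1])
    bp = P[:, band, :].sum(axis=1)
    fb = freqs[band]
    dom = fb[np.argmax(P[:, band, :], axis=1)] if band.any() else np.zeros((n, 4))
    dom = np.where(bp > 1e-16, dom, 0.0)
    # inter-axis Pearson correlations; zero-variance axes contribute 0
    xc = X - X.mean(axis=1, keepdims=True)
    cov = np.einsum("nwi,nwj->nij", xc, xc) / w
    s = np.sqrt(np.clip(np.einsum("nii->ni", cov), 1e-30, None))
    denom = s[:, :, None] * s[:, None, :]
    corr = np.where(denom > 1e-24, cov / denom, 0.0)
    cols = [mean, sd, dom, bp]
    out = np.empty((n, len(FEATURE_NAMES)))
    for ci in range(4):  # channel-major ordering to match FEATURE_NAMES
        for si, arr in enumerate(cols):
            out[:, ci * 4 + si] = arr[:, ci]
    out[:, 16] = corr[:, 0, 1]
    out[:, 17] = corr[:, 0, 2]
    out[:, 18] = corr[:, 1, 2]
    return out


def _extract_features(ws: WindowSet) -> np.ndarray:
    fs = ws.rec.sample_rate_hz
    lengths = ws.idx[:, 1] - ws.idx[:, 0]
    out = np.empty((len(ws), len(FEATURE_NAMES)))
    for w in np.unique(lengths):
        sel = np.nonzero(lengths == w)[0]
        X = np.stack([ws.rec.acc_g[ws.idx[k, 0]:ws.idx[k, 1]] for k in sel])
        out[sel] = _features_for_length(X, fs)
    return out


def extract_window_features(samples: np.ndarray, sample_rate_hz: float = 20.0) -> np.ndarray:
    """Features for a single window given raw ``(w, 3)`` samples."""
    return _features_for_length(np.asarray(samples, dtype=float)[None], sample_rate_hz)[0]


@dataclasses.dataclass(frozen=True)
class SplitProtocol:
    """Disjoint subject-wise train/validation/test assignment."""

    train: frozenset
    val: frozenset
    test: frozenset

    def __post_init__(self) -> None:
        if (self.train & self.val) or (self.train & self.test) or (self.val & self.test):
            raise ProtocolError("train/val/test subject sets must be disjoint")
        if not self.train:
            raise ProtocolError("training set is empty")

    @classmethod
    def leave_one_out_per_source(cls, sources: Mapping[str, str], seed: int = 0) -> "SplitProtocol":
        """Hold out one validation and one test subject from every source."""
        rng = np.random.default_rng(seed)
        val, test, train = set(), set(), set()
        by_src: dict[str, list[str]] = {}
        for sid, src in sources.items():
            by_src.setdefault(src, []).append(sid)
        for src, sids in sorted(by_src.items()):
            if len(sids) < 3:
                raise ProtocolError(f"source {src!r} needs >= 3 subjects")
            sids = sorted(sids)
            picks = rng.choice(len(sids), size=2, replace=False)
            val.add(sids[picks[0]])
            test.add(sids[picks[1]])
            train.update(s for i, s in enumerate(sids) if i not in picks)
        return cls(frozenset(train), frozenset(val), frozenset(test))


@dataclasses.dataclass
class ClassifierSpec:
    """Classifier choice.  ``baseline_features`` is the supported backend;
    ``conv_recurrent`` names a 9-layer convolutional-recurrent plug-in slot
    (4 conv + 2 recurrent + 2 dense + softmax) that is not implemented in
    this release."""

    kind: str = "baseline_features"
    C: float = 1.0
    max_iter: int = 2000
    n_layers: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("baseline_features", "conv_recurrent"):
            raise ConfigError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "conv_recurrent" and self.n_layers != 9:
            raise ConfigError("conv_recurrent variant is defined as a 9-layer network")


@dataclasses.dataclass
class HARModel:
    pipeline: Pipeline
    classes_: np.ndarray
    duration_s: float
    stride_s: float
    sample_rate_hz: float

    def predict_windows(self, ws: WindowSet) -> "ActivityLabelSequence":
        return predict_windows(self, ws)


@dataclasses.dataclass
class ValidationReport:
    binary_accuracy: float
    fine_accuracy: float
    stationary_recall: float
    ambulatory_recall: float
    n_windows: int


@dataclasses.dataclass
class ActivityLabelSequence:
    """Window-level labels plus the per-sample binary bridge."""

    windows: pd.DataFrame          # start_s, end_s, fine_label, binary_label
    sample_code: np.ndarray        # int8 per sample of the source recording
    sample_rate_hz: float

    def classified_time_s(self) -> dict[str, float]:
        period = 1.0 / self.sample_rate_hz
        amb = int(np.sum(self.sample_code == states.AMBULATORY))
        stat = int(np.sum(self.sample_code == states.STATIONARY))
        return {
            "ambulatory_s": amb * period,
            "stationary_s": stat * period,
            "classified_s": (amb + stat) * period,
        }


def _assemble(windowsets: Iterable[WindowSet]):
    X, y, subj = [], [], []
    for ws in windowsets:
        keep = ws.true_fine >= 0
        if not keep.any():
            continue
        feats = ws.features()[keep]
        X.append(feats)
        y.append(ws.true_fine[keep])
        subj.extend([ws.patient_id] * int(keep.sum()))
    if not X:
        raise ProtocolError("no labeled windows supplied")
    return np.vstack(X), np.concatenate(y), np.array(subj)


def _binary(y_fine: np.ndarray) -> np.ndarray:
    return np.array([states.binary_of_code(c) for c in y_fine], dtype=np.int8)


def train_classifier(
    windowsets: Sequence[WindowSet],
    spec: ClassifierSpec,
    split: SplitProtocol,
) -> tuple[HARModel, ValidationReport]:
    """Fit the window classifier on training subjects only.

    Model selection (here: the converged fit itself) sees validation
    subjects only through the returned report; test subjects are untouched.
    """
    if spec.kind == "conv_recurrent":
        raise NotImplementedError(
            "the 9-layer convolutional-recurrent variant is a plug-in slot; "
            "use kind='baseline_features'"
        )
    subjects = {ws.patient_id for ws in windowsets}
    unknown = subjects - (split.train | split.val | split.test)
    if unknown:
        raise ProtocolError(f"subjects missing from split: {sorted(unknown)}")
    X, y, subj = _assemble(windowsets)
    in_train = np.isin(subj, sorted(split.train))
    in_val = np.isin(subj, sorted(split.val))
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=spec.C, max_iter=spec.max_iter, random_state=spec.seed)),
        ]
    )
    pipe.fit(X[in_train], y[in_train])
    model = HARModel(
        pipeline=pipe,
        classes_=pipe.named_steps["clf"].classes_,
        duration_s=windowsets[0].duration_s,
        stride_s=windowsets[0].stride_s,
        sample_rate_hz=windowsets[0].rec.sample_rate_hz,
    )
    report = _evaluate(pipe, X[in_val], y[in_val]) if in_val.any() else None
    return model, report


def _evaluate(pipe: Pipeline, X: np.ndarray, y: np.ndarray) -> ValidationReport:
    pred = pipe.predict(X)
    yb, pb = _binary(y), _binary(pred)
    stat = yb == states.STATIONARY
    amb = yb == states.AMBULATORY
    return ValidationReport(
        binary_accuracy=float(np.mean(yb == pb)),
        fine_accuracy=float(np.mean(y == pred)),
        stationary_recall=float(np.mean(pb[stat] == states.STATIONARY)) if stat.any() else np.nan,
        ambulatory_recall=float(np.mean(pb[amb] == states.AMBULATORY)) if amb.any() else np.nan,
        n_windows=int(y.size),
    )


def evaluate_model(model: HARModel, windowsets: Sequence[WindowSet]) -> ValidationReport:
    """Window-level accuracy of a trained model on labeled window sets."""
    X, y, _ = _assemble(windowsets)
    return _evaluate(model.pipeline, X, y)


def predict_windows(model: HARModel, ws: WindowSet) -> ActivityLabelSequence:
    """Label windows and bridge to per-sample binary codes.

    Per-sample code = majority binary label across the windows covering the
    sample; on a tie the earliest covering window wins; samples covered by
    no window stay unclassified.
    """
    if abs(model.sample_rate_hz - ws.rec.sample_rate_hz) > 1e-9:
        raise ConfigError("model and windows were built at different sample rates")
    n = ws.rec.n_samples
    if len(ws) == 0:
        return ActivityLabelSequence(
            pd.DataFrame(columns=["start_s", "end_s", "fine_label", "binary_label"]),
            np.full(n, states.UNCLASSIFIED, np.int8),
            ws.rec.sample_rate_hz,
        )
    fine_pred = model.pipeline.predict(ws.features())
    binary_pred = _binary(fine_pred)
    votes = np.zeros((n, 2), dtype=np.int32)
    first = np.full(n, states.UNCLASSIFIED, dtype=np.int8)
    order = np.argsort(ws.start_s, kind="stable")
    for k in order[::-1]:  # reversed: earliest window writes last
        i0, i1 = ws.idx[k]
        first[i0:i1] = binary_pred[k]
    for k in order:
        i0, i1 = ws.idx[k]
        votes[i0:i1, int(binary_pred[k])] += 1
    code = np.full(n, states.UNCLASSIFIED, dtype=np.int8)
    covered = votes.sum(axis=1) > 0
    amb_wins = votes[:, states.AMBULATORY] > votes[:, states.STATIONARY]
    stat_wins = votes[:, states.STATIONARY] > votes[:, states.AMBULATORY]
    code[covered & amb_wins] = states.AMBULATORY
    code[covered & stat_wins] = states.STATIONARY
    tie = covered & ~amb_wins & ~stat_wins
    code[tie] = first[tie]
    frame = pd.DataFrame(
        {
            "start_s": ws.start_s,
            "end_s": ws.start_s + ws.duration_s,
            "fine_label": [states.FINE_NAME[int(c)] for c in fine_pred],
            "binary_label": [states.BINARY_NAME[int(b)] for b in binary_pred],
        }
    )
    return ActivityLabelSequence(frame, code, ws.rec.sample_rate_hz)


def write_labels(seq: ActivityLabelSequence, path) -> None:
    seq.windows.to_csv(path, index=False)


def labels_frame_to_sample_code(
    frame: pd.DataFrame, time_s: np.ndarray, sample_rate_hz: float
) -> np.ndarray:
    """Rebuild per-sample binary codes from a labels CSV (windows table)."""
    n = len(time_s)
    votes = np.zeros((n, 2), dtype=np.int32)
    first = np.full(n, states.UNCLASSIFIED, dtype=np.int8)
    frame = frame.sort_values("start_s", kind="stable")
    binary = frame["binary_label"].map({"stationary": states.STATIONARY, "ambulatory": states.AMBULATORY})
    i0s = np.searchsorted(time_s, frame["start_s"].to_numpy() - 1e-9, side="left")
    i1s = np.searchsorted(time_s, frame["end_s"].to_numpy() - 1e-9, side="left")
    for i0, i1, b in zip(i0s[::-1], i1s[::-1], binary.to_numpy()[::-1]):
        first[i0:i1] = b
    for i0, i1, b in zip(i0s, i1s, binary.to_numpy()):
        votes[i0:i1, int(b)] += 1
    code = np.full(n, states.UNCLASSIFIED, dtype=np.int8)
    covered = votes.sum(axis=1) > 0
    amb_wins = votes[:, states.AMBULATORY] > votes[:, states.STATIONARY]
    stat_wins = votes[:, states.STATIONARY] > votes[:, states.AMBULATORY]
    code[covered & amb_wins] = states.AMBULATORY
    code[covered & stat_wins] = states.STATIONARY
    tie = covered & ~amb_wins & ~stat_wins
    code[tie] = first[tie]
    return code
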