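"""Synthetic wrist-actigraphy cohorts with known ground truth.

The generator stands in for private trial data.  It produces, per patient:

* a multi-day activity schedule (minutes-scale bouts of eight activity
  states plus explicit ``non_wear`` gaps tuned to a target monitoring
  ratio, ~0.74 by default);
* a 20 Hz tri-axial acceleration signal: unit gravity along a per-state
  orientation, Gaussian device noise, a fundamental-plus-harmonic gait
  oscillation during ambulatory states, and amplitude-modulated noise
  bursts (gestures) during stationary states.  Idle per-axis noise SD is
  kept below the 0.01 g detector separatrix and burst SD above it;
* ground-truth gesture events.  Each planted burst is recorded twice over:
  the physical burst interval (``burst_start_s``/``burst_end_s``) and the
  window-support event interval (``start_s``/``end_s``) — the burst dilated
  by one moving window minus one sample per side, clipped to its stationary
  entry — which is the interval a window-based detector ideally reports;
* clinical scores (BNSS total/apathy/diminished expression, PANSS
  NSFS/PSFS) and effort-choice trial logs, coupled to the behavioural
  latents through a Gaussian copula with configurable rank-correlation
  targets, so that downstream correlation analyses can recover planted
  effects.

Bursts are placed as a hard-core thinned Poisson process (minimum
separation, margin from entry edges) so that neighbouring events stay
separable under the sub-second gap-merge rule.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import states
from .errors import ConfigError
from .io import AccelerometerRecording

# per-state gait model: fundamental frequency (Hz), oscillation amplitude (g)
GAIT_MODEL: dict[str, tuple[float, float]] = {
    "walking": (1.8, 0.25),
    "climbing_stairs": (1.4, 0.35),
    "cycling": (1.0, 0.12),
    "jogging": (2.6, 0.50),
}

# gravity orientation per stationary state (unit vectors; wrist poses differ)
_STATIONARY_ORIENT: dict[str, np.ndarray] = {
    "sitting": np.array([0.0, 0.0, 1.0]),
    "standing": np.array([0.0, np.sin(np.pi / 12), np.cos(np.pi / 12)]),
    "lying_down": np.array([1.0, 0.0, 0.0]),
    "hand_work": np.array([np.sin(np.pi / 8), 0.0, np.cos(np.pi / 8)]),
}

DAY_S = 86_400


@dataclasses.dataclass(frozen=True)
class ActivityScheduleEntry:
    state: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.state not in states.ALL_STATES:
            raise ConfigError(f"unknown state {self.state!r}")
        if self.end_s <= self.start_s:
            raise ConfigError("entry must have positive duration")


@dataclasses.dataclass
class SignalModelParams:
    """Signal-model and schedule parameters (units in field names).

    ``idle_noise_sd_g`` must stay below 0.01 g and ``gesture_amp_sd_g``
    above it: the moving-SD threshold separates idle wrist noise from
    gesture bursts only when the generator honours that premise.
    """

    sample_rate_hz: float = 20.0
    gait_freq_hz: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {s: f for s, (f, _) in GAIT_MODEL.items()}
    )
    gait_amp_g: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {s: a for s, (_, a) in GAIT_MODEL.items()}
    )
    ambulatory_noise_sd_g: float = 0.05
    idle_noise_sd_g: float = 0.005
    gesture_rate_per_h: float = 6.0
    gesture_dur_s_range: tuple[float, float] = (0.5, 5.0)
    gesture_amp_sd_g: float = 0.05
    gesture_margin_s: float = 6.0
    gesture_min_sep_s: float = 3.0
    gravity_g: float = 1.0
    target_monitoring_ratio: float = 0.74
    ambulatory_frac: float = 0.20
    wear_bout_s_range: tuple[float, float] = (600.0, 2400.0)
    nonwear_bout_s_range: tuple[float, float] = (1800.0, 7200.0)
    truth_window_s: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if not (self.idle_noise_sd_g < 0.01 < self.gesture_amp_sd_g):
            raise ConfigError(
                "detectability premise violated: need idle_noise_sd_g < 0.01 g "
                "< gesture_amp_sd_g"
            )
        if not 0.0 <= self.target_monitoring_ratio <= 1.0:
            raise ConfigError("target_monitoring_ratio must be in [0, 1]")
        if not 0.0 <= self.ambulatory_frac <= 1.0:
            raise ConfigError("ambulatory_frac must be in [0, 1]")
        lo, hi = self.gesture_dur_s_range
        if not 0 < lo <= hi:
            raise ConfigError("gesture_dur_s_range must be positive and ordered")


def generate_schedule(
    days: int, params: SignalModelParams, seed: int | None = None
) -> list[ActivityScheduleEntry]:
    """Draw a bout-level activity schedule covering exactly ``days`` x 24 h.

    Bouts have integer-second durations (so entries align with the 20 Hz
    sample grid).  A bout is ``non_wear`` with the probability that makes the
    expected non-wear *time* fraction equal ``1 - target_monitoring_ratio``
    under the configured bout-duration distributions; wear bouts are
    ambulatory with probability ``ambulatory_frac``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    total = days * DAY_S
    f_nw = 1.0 - params.target_monitoring_ratio
    mean_w = np.mean(params.wear_bout_s_range)
    mean_n = np.mean(params.nonwear_bout_s_range)
    # bout-type fraction achieving the target non-wear *time* fraction;
    # corrected for the no-consecutive-non-wear constraint (2-state chain:
    # stationary non-wear bout share q relates to the transition prob p via
    # q = p / (1 + p))
    q_nw = 0.0 if f_nw == 0 else (f_nw * mean_w) / (mean_n * (1 - f_nw) + f_nw * mean_w)
    p_nw = q_nw / (1.0 - q_nw) if q_nw < 1.0 else 1.0

    entries: list[ActivityScheduleEntry] = []
    t = 0
    prev_nonwear = False
    while t < total:
        nonwear = (not prev_nonwear) and (rng.random() < p_nw)
        if nonwear:
            dur = int(round(rng.uniform(*params.nonwear_bout_s_range)))
            state = states.NON_WEAR
        else:
            dur = int(round(rng.uniform(*params.wear_bout_s_range)))
            if rng.random() < params.ambulatory_frac:
                state = rng.choice(states.AMBULATORY_STATES, p=[0.55, 0.15, 0.15, 0.15])
            else:
                state = rng.choice(states.STATIONARY_STATES, p=[0.4, 0.2, 0.3, 0.1])
        dur = min(dur, total - t)
        entries.append(ActivityScheduleEntry(str(state), float(t), float(t + dur)))
        t += dur
        prev_nonwear = nonwear
    return entries


def schedule_sample_labels(
    schedule: list[ActivityScheduleEntry], time_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (fine_code, binary_code) ground-truth labels for given times."""
    starts = np.array([e.start_s for e in schedule])
    ends = np.array([e.end_s for e in schedule])
    idx = np.searchsorted(starts, np.asarray(time_s), side="right") - 1
    fine = np.full(len(time_s), -1, dtype=np.int8)
    binary = np.full(len(time_s), states.UNCLASSIFIED, dtype=np.int8)
    for k, e in enumerate(schedule):
        sel = (idx == k) & (np.asarray(time_s) < ends[k])
        if e.state == states.NON_WEAR:
            continue
        fine[sel] = states.FINE_CODE[e.state]
        binary[sel] = states.BINARY_OF[e.state]
    return fine, binary


def _place_bursts(
    rng: np.random.Generator,
    stationary_entries: list[ActivityScheduleEntry],
    params: SignalModelParams,
    exact_n_events: int | None,
) -> list[tuple[int, float, float]]:
    """Place (entry_index, start_s, dur_s) bursts with hard-core separation."""
    lo, hi = params.gesture_dur_s_range
    margin = params.gesture_margin_s
    usable = [
        max(0.0, (e.end_s - e.start_s) - 2 * margin - hi) for e in stationary_entries
    ]
    total_usable = sum(usable)
    if total_usable <= 0:
        if exact_n_events:
            raise ConfigError("no stationary time available to plant events in")
        return []
    if exact_n_events is None:
        stat_h = sum(e.end_s - e.start_s for e in stationary_entries) / 3600.0
        n = rng.poisson(params.gesture_rate_per_h * stat_h)
    else:
        n = exact_n_events
    placed: list[tuple[int, float, float]] = []
    occupied: dict[int, list[tuple[float, float]]] = {}
    weights = np.array(usable) / total_usable
    attempts = 0
    while len(placed) < n and attempts < 200 * max(n, 1):
        attempts += 1
        k = int(rng.choice(len(stationary_entries), p=weights))
        e = stationary_entries[k]
        dur = float(rng.uniform(lo, hi))
        start = float(rng.uniform(e.start_s + margin, e.end_s - margin - dur))
        ok = all(
            start - (b0 + bd) >= params.gesture_min_sep_s or b0 - (start + dur) >= params.gesture_min_sep_s
            for b0, bd in occupied.get(k, [])
        )
        if ok:
            occupied.setdefault(k, []).append((start, dur))
            placed.append((k, start, dur))
    if exact_n_events is not None and len(placed) < n:
        raise ConfigError("could not place the requested number of gesture events")
    return placed


def synthesize_signal(
    schedule: list[ActivityScheduleEntry],
    params: SignalModelParams,
    seed: int | None = None,
    patient_id: str = "P000",
    exact_n_events: int | None = None,
) -> tuple[AccelerometerRecording, pd.DataFrame]:
    """Render the schedule into a 20 Hz recording plus ground-truth events.

    Returns the recording and a truth table with columns ``start_s``,
    ``end_s`` (window-support event interval), ``burst_start_s``,
    ``burst_end_s``, ``n_samples`` and ``power_g2`` (computed from the
    rendered samples of the physical burst).
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fs = params.sample_rate_hz
    dt = 1.0 / fs

    stat_entries = [e for e in schedule if e.state in states.STATIONARY_STATES]
    bursts = _place_bursts(rng, stat_entries, params, exact_n_events)
    bursts_by_entry: dict[int, list[tuple[float, float]]] = {}
    for k, start, dur in bursts:
        bursts_by_entry.setdefault(k, []).append((start, dur))

    times, accs = [], []
    truth_rows = []
    stat_i = -1
    for e in schedule:
        if e.state == states.NON_WEAR:
            continue
        n = int(round((e.end_s - e.start_s) * fs))
        if n == 0:
            continue
        t = e.start_s + np.arange(n) * dt
        if e.state in states.AMBULATORY_STATES:
            f = params.gait_freq_hz[e.state] * (1.0 + 0.05 * rng.standard_normal())
            amp = params.gait_amp_g[e.state]
            ph = rng.uniform(0, 2 * np.pi, size=3)
            acc = rng.normal(0.0, params.ambulatory_noise_sd_g, size=(n, 3))
            acc[:, 2] += params.gravity_g + amp * np.sin(2 * np.pi * f * t + ph[0])
            acc[:, 2] += 0.3 * amp * np.sin(4 * np.pi * f * t + ph[1])
            acc[:, 0] += 0.4 * amp * np.sin(2 * np.pi * f * t + ph[2])
        else:
            stat_i += 1
            orient = _STATIONARY_ORIENT[e.state]
            acc = np.broadcast_to(params.gravity_g * orient, (n, 3)).copy()
            if params.idle_noise_sd_g > 0:
                acc += rng.normal(0.0, params.idle_noise_sd_g, size=(n, 3))
            for b_start, b_dur in sorted(bursts_by_entry.get(stat_i, [])):
                j0 = int(round((b_start - e.start_s) * fs))
                j1 = int(round((b_start + b_dur - e.start_s) * fs))
                j1 = max(j1, j0 + 2)
                acc[j0:j1] += rng.normal(0.0, params.gesture_amp_sd_g, size=(j1 - j0, 3))
                m = np.linalg.norm(acc[j0:j1], axis=1)
                burst_t0 = e.start_s + j0 * dt
                burst_t1 = e.start_s + j1 * dt
                dilate = params.truth_window_s - dt
                truth_rows.append(
                    {
                        "start_s": max(e.start_s, burst_t0 - dilate),
                        "end_s": min(e.end_s, burst_t1 + dilate),
                        "burst_start_s": burst_t0,
                        "burst_end_s": burst_t1,
                        "n_samples": j1 - j0,
                        "power_g2": float(np.sum((m - m.mean()) ** 2)),
                    }
                )
        times.append(t)
        accs.append(acc)

    if times:
        time_s = np.concatenate(times)
        acc_g = np.vstack(accs)
        order = np.argsort(time_s, kind="stable")
        time_s, acc_g = time_s[order], acc_g[order]
    else:
        time_s, acc_g = np.empty(0), np.empty((0, 3))
    span_h = (schedule[-1].end_s if schedule else 0.0) / 3600.0
    rec = AccelerometerRecording(patient_id, fs, time_s, acc_g, study_span_h=span_h)
    truth = pd.DataFrame(
        truth_rows,
        columns=["start_s", "end_s", "burst_start_s", "burst_end_s", "n_samples", "power_g2"],
    ).sort_values("start_s", ignore_index=True)
    return rec, truth


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

#: latent variable order used by the copula
LATENTS = ("gesture_rate", "activity_ratio", "bnss_total", "high_effort")

DEFAULT_COUPLING: dict[tuple[str, str], float] = {
    ("gesture_rate", "bnss_total"): -0.438,
    ("activity_ratio", "high_effort"): 0.58,
}

DEFAULT_SCORE_RANGES: dict[str, tuple[int, int]] = {
    "bnss_total": (13, 78),
    "bnss_apathy": (0, 42),
    "bnss_dimexp": (0, 36),
    "panss_nsfs": (7, 49),
    "panss_psfs": (8, 56),
}


@dataclasses.dataclass
class CohortConfig:
    """Cohort size, latent rank-correlation targets and score ranges."""

    n_patients: int = 33
    days_per_patient: int = 28
    latent_coupling: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    score_ranges: dict[str, tuple[int, int]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SCORE_RANGES)
    )
    gesture_rate_range_per_h: tuple[float, float] = (3.0, 30.0)
    ambulatory_frac_range: tuple[float, float] = (0.05, 0.35)
    monitoring_ratio_mean: float = 0.74
    monitoring_ratio_sd: float = 0.08
    trials_per_cell: int = 2
    min_wear_h: float = 8.0
    signal: SignalModelParams = dataclasses.field(default_factory=SignalModelParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 3:
            raise ConfigError("n_patients must be >= 3")
        for pair, rho in self.latent_coupling.items():
            if abs(rho) > 1:
                raise ConfigError(f"rank-correlation target {pair} out of [-1, 1]")
            for name in pair:
                if name not in LATENTS:
                    raise ConfigError(f"unknown latent {name!r}; known: {LATENTS}")


def _copula_correlation(coupling: dict[tuple[str, str], float]) -> np.ndarray:
    """Pearson correlation of the Gaussian copula achieving the rank targets.

    Uses the exact bivariate-normal relation rho = 2 sin(pi * rho_s / 6);
    raises ConfigError when the assembled matrix is not positive
    semi-definite.
    """
    k = len(LATENTS)
    R = np.eye(k)
    for (a, b), rho_s in coupling.items():
        i, j = LATENTS.index(a), LATENTS.index(b)
        if i == j:
            raise ConfigError("coupling targets must link two distinct latents")
        R[i, j] = R[j, i] = 2.0 * np.sin(np.pi * rho_s / 6.0)
    if np.linalg.eigvalsh(R).min() < -1e-9:
        raise ConfigError("infeasible latent coupling: matrix not positive semi-definite")
    return R


def _sample_copula(rng: np.random.Generator, R: np.ndarray, n: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return rng.standard_normal((n, R.shape[0])) @ L.T


def _lerp(lo: float, hi: float, u: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * u


@dataclasses.dataclass
class SyntheticCohort:
    """Generated cohort: per-patient parameters, scores, trials, summaries."""

    config: CohortConfig
    patients: pd.DataFrame
    scores: pd.DataFrame
    trials: pd.DataFrame
    daily: pd.DataFrame
    schedules: dict[str, list[ActivityScheduleEntry]] | None = None
    recordings: dict[str, AccelerometerRecording] | None = None
    gesture_truth: dict[str, pd.DataFrame] | None = None

    def features_table(self) -> pd.DataFrame:
        """Per-patient digital features from the daily summary path."""
        rows = []
        for pid, grp in self.daily.groupby("patient_id", sort=True):
            ok = grp[grp["wear_h"] >= self.config.min_wear_h]
            rows.append(
                {
                    "patient_id": pid,
                    "activity_time_ratio": float(
                        self.patients.set_index("patient_id").loc[pid, "observed_activity_ratio"]
                    ),
                    "median_daily_gesture_count": float(ok["count"].median()) if len(ok) else np.nan,
                    "gesture_power_agg": float(ok["power_med_g2"].median()) if len(ok) else np.nan,
                    "monitoring_ratio": float(grp["wear_h"].sum() / (24.0 * len(grp))),
                    "n_days_used": int(len(ok)),
                }
            )
        return pd.DataFrame(rows)

    def cohort_table(self) -> pd.DataFrame:
        """Features joined to clinical scores and the effort-choice score."""
        from .clinical import score_effort_choice

        feats = self.features_table()
        effort = (
            self.trials.groupby("patient_id", sort=True)
            .apply(score_effort_choice, include_groups=False)
            .rename("high_effort_pct")
            .reset_index()
        )
        return feats.merge(self.scores, on="patient_id").merge(effort, on="patient_id")


def generate_cohort(
    config: CohortConfig, with_recordings: bool = False
) -> SyntheticCohort:
    """Draw a full synthetic cohort.

    Latent traits come from a Gaussian copula with the configured
    rank-correlation targets.  Daily gesture counts are Poisson in the
    patient's rate and stationary wear time; effort-choice trials are
    Bernoulli with hard-choice probability monotone in the motivation
    latent.  With ``with_recordings=True`` the 20 Hz signal and ground-truth
    events are rendered for every patient (intended for demo-scale cohorts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    Z = _sample_copula(rng, _copula_correlation(config.latent_coupling), n)
    U = sps.norm.cdf(Z)

    lo, hi = config.gesture_rate_range_per_h
    rate = np.exp(_lerp(np.log(lo), np.log(hi), U[:, 0]))
    amb = _lerp(*config.ambulatory_frac_range, U[:, 1])
    mr = np.clip(rng.normal(config.monitoring_ratio_mean, config.monitoring_ratio_sd, n), 0.2, 1.0)

    def bounded_score(z: np.ndarray, mean: float, sd: float, key: str) -> np.ndarray:
        lo_s, hi_s = config.score_ranges[key]
        return np.clip(np.rint(mean + sd * z), lo_s, hi_s).astype(int)

    zb = Z[:, 2]
    mix = lambda a, z: a * z + np.sqrt(1 - a * a) * rng.standard_normal(n)  # noqa: E731
    scores = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "bnss_total": bounded_score(zb, 36.0, 11.5, "bnss_total"),
            "bnss_apathy": bounded_score(mix(0.75, zb), 14.0, 6.0, "bnss_apathy"),
            "bnss_dimexp": bounded_score(mix(0.85, zb), 12.0, 5.0, "bnss_dimexp"),
            "panss_nsfs": bounded_score(mix(0.70, zb), 23.0, 3.5, "panss_nsfs"),
            "panss_psfs": bounded_score(rng.standard_normal(n), 19.2, 4.8, "panss_psfs"),
        }
    )

    # effort-choice trials: factorial presses x points x probability
    p_base = _lerp(0.05, 0.95, U[:, 3])
    cells = list(itertools.product((100, 120, 150), (3, 5, 7), (0.5, 1.0)))
    trial_rows = []
    for i in range(n):
        logit = np.log(p_base[i] / (1 - p_base[i]))
        for presses, points, prob in cells * config.trials_per_cell:
            lp = logit + 0.15 * (points - 5) / 2 - 0.10 * (presses - 120) / 30 + 0.5 * (prob - 0.75) * 4
            hard = rng.random() < 1.0 / (1.0 + np.exp(-lp))
            trial_rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "choice": "hard" if hard else "easy",
                    "effort_presses": presses if hard else 20,
                    "reward_points": points if hard else 1,
                    "reward_probability": prob,
                    "offered_presses": presses,
                    "offered_points": points,
                }
            )
    trials = pd.DataFrame(trial_rows)

    # daily summaries (fast statistical path consistent with the signal model)
    d = config.days_per_patient
    daily_rows = []
    log_p0 = np.log(0.1)
    for i in range(n):
        wear = np.clip(rng.normal(24.0 * mr[i], 2.0, d), 0.0, 24.0)
        stat_h = wear * (1.0 - amb[i])
        counts = rng.poisson(rate[i] * stat_h)
        pow_med = np.exp(rng.normal(log_p0 + 0.5 * Z[i, 0], 0.3, d))
        for j in range(d):
            daily_rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "date_index": j,
                    "wear_h": wear[j],
                    "count": int(counts[j]),
                    "power_med_g2": pow_med[j],
                }
            )
    daily = pd.DataFrame(daily_rows)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "gesture_rate_per_h": rate,
            "ambulatory_frac": amb,
            "monitoring_ratio": mr,
            "p_high_effort_base": p_base,
            "observed_activity_ratio": np.clip(amb + rng.normal(0, 0.01, n), 0.0, 1.0),
        }
    )

    schedules = recordings = truths = None
    if with_recordings:
        schedules, recordings, truths = {}, {}, {}
        child = np.random.SeedSequence(config.seed).spawn(n)
        for i in range(n):
            pid = f"P{i:03d}"
            p = dataclasses.replace(
                config.signal,
                gesture_rate_per_h=float(rate[i]),
                ambulatory_frac=float(amb[i]),
                target_monitoring_ratio=float(mr[i]),
            )
            s1, s2 = (int(x) for x in child[i].generate_state(2) % (2**31))
            sched = generate_schedule(d, p, seed=s1)
            rec, truth = synthesize_signal(sched, p, seed=s2, patient_id=pid)
            schedules[pid], recordings[pid], truths[pid] = sched, rec, truth

    return SyntheticCohort(
        config=config,
        patients=patients,
        scores=scores,
        trials=trials,
        daily=daily,
        schedules=schedules,
        recordings=recordings,
        gesture_truth=truths,
    )


def generate_har_training_set(
    n_per_source: int = 9,
    minutes: float = 20.0,
    seed: int = 0,
    params: SignalModelParams | None = None,
    duration_s: float = 5.0,
    stride_s: float = 5.0,
):
    """Two synthetic "sources" of annotated subjects for HAR training.

    Sources differ mildly (noise level, gait-frequency shift) to emulate
    device/protocol domain shift between public corpora.  Returns
    ``(windowsets, sources)`` where ``sources`` maps subject id -> source
    name; windows carry majority ground-truth fine labels.
    """
    from .har import window_signal

    base = params or SignalModelParams()
    windowsets, sources = [], {}
    ss = np.random.SeedSequence(seed).spawn(2 * n_per_source)
    k = 0
    for src, (noise_mult, freq_mult) in (("src_a", (1.0, 1.0)), ("src_b", (1.5, 1.1))):
        for _ in range(n_per_source):
            sid = f"{src}_s{k:02d}"
            p = dataclasses.replace(
                base,
                ambulatory_noise_sd_g=base.ambulatory_noise_sd_g * noise_mult,
                gait_freq_hz={s: f * freq_mult for s, f in base.gait_freq_hz.items()},
                target_monitoring_ratio=1.0,
                ambulatory_frac=0.5,
                wear_bout_s_range=(60.0, 180.0),
            )
            s1, s2 = (int(x) for x in ss[k].generate_state(2) % (2**31))
            sched = generate_schedule(1, p, seed=s1)
            sched = _truncate_schedule(sched, minutes * 60.0)
            rec, _ = synthesize_signal(sched, p, seed=s2, patient_id=sid)
            ws = window_signal(rec, duration_s=duration_s, stride_s=stride_s, annotations=sched)
            windowsets.append(ws)
            sources[sid] = src
            k += 1
    return windowsets, sources


def _truncate_schedule(
    schedule: list[ActivityScheduleEntry], total_s: float
) -> list[ActivityScheduleEntry]:
    out = []
    for e in schedule:
        if e.start_s >= total_s:
            break
        out.append(ActivityScheduleEntry(e.state, e.start_s, min(e.end_s, total_s)))
    return out


# ---------------------------------------------------------------------------
# plain-text writers (documented CSV dialects)
# ---------------------------------------------------------------------------

def write_schedule(schedule: list[ActivityScheduleEntry], path: str | Path) -> None:
    pd.DataFrame(
        [(e.state, e.start_s, e.end_s) for e in schedule],
        columns=["state", "start_s", "end_s"],
    ).to_csv(path, index=False)


def read_schedule(path: str | Path) -> list[ActivityScheduleEntry]:
    df = pd.read_csv(path)
    return [
        ActivityScheduleEntry(r.state, float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]


def write_gesture_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)
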