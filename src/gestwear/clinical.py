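"""Clinical scores and effort-choice task scoring.

The effort-choice task offers, per trial, an easy option (press a balloon
20 times for 1 point) or a hard option (100/120/150 presses for 3/5/7
points) with a stated reward probability of 50% or 100%.  Motivated
behaviour is summarised as the percentage of hard choices among trials
offering 5 or 7 points at 100% reward probability; cumulated points
convert to a bonus at $1 per completed set of 20 points.
"""

from __future__ import annotations

import dataclasses
import math

import pandas as pd

from .errors import ConfigError, FormatError

HARD_PRESSES = (100, 120, 150)
HARD_POINTS = (3, 5, 7)
REWARD_PROBS = (0.5, 1.0)
QUALIFYING_POINTS = (5, 7)

TRIAL_COLUMNS = ("patient_id", "choice", "effort_presses", "reward_points", "reward_probability")


@dataclasses.dataclass
class ClinicalScores:
    """Scale scores used in the correlation stage (instrument conventions:
    higher = more severe)."""

    patient_id: str
    bnss_total: int
    bnss_apathy: int
    bnss_dimexp: int
    panss_nsfs: int
    panss_psfs: int
    cgis: int | None = None

    def validate(self, ranges: dict[str, tuple[int, int]]) -> None:
        for key, (lo, hi) in ranges.items():
            v = getattr(self, key, None)
            if v is not None and not lo <= v <= hi:
                raise ConfigError(f"{key}={v} outside instrument range [{lo}, {hi}]")


def validate_trials(trials: pd.DataFrame) -> None:
    """Enforce the task's structural invariants on a trials table."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trials table missing columns {missing}")
    easy = trials["choice"] == "easy"
    hard = trials["choice"] == "hard"
    if not (easy | hard).all():
        raise FormatError("choice must be 'easy' or 'hard'")
    if not (trials.loc[easy, "effort_presses"] == 20).all() or not (
        trials.loc[easy, "reward_points"] == 1
    ).all():
        raise FormatError("easy trials must have 20 presses and 1 point")
    if not trials.loc[hard, "effort_presses"].isin(HARD_PRESSES).all():
        raise FormatError(f"hard presses must be one of {HARD_PRESSES}")
    if not trials.loc[hard, "reward_points"].isin(HARD_POINTS).all():
        raise FormatError(f"hard points must be one of {HARD_POINTS}")
    if not trials["reward_probability"].isin(REWARD_PROBS).all():
        raise FormatError(f"reward probability must be one of {REWARD_PROBS}")


def score_effort_choice(trials: pd.DataFrame) -> float:
    """Percent hard choices among 5/7-point, 100%-probability trials.

    Returns NaN (missing-score marker) when no trial qualifies.  The
    qualifying filter applies to the *offered* hard reward: the easy choice
    on a qualifying offer still counts in the denominator, so the offered
    points must be recorded per trial regardless of the choice made.
    Trials tables produced by this package record the offered hard reward
    in ``reward_points`` only for hard choices; qualifying offers are
    therefore identified by probability and offered points where available,
    falling back to the recorded reward.
    """
    qualifying = (trials["reward_probability"] == 1.0) & (
        trials.get("offered_points", trials["reward_points"]).isin(QUALIFYING_POINTS)
    )
    q = trials[qualifying]
    if len(q) == 0:
        return math.nan
    return 100.0 * float((q["choice"] == "hard").mean())


def compute_bonus(points_total: int) -> int:
    """Dollar bonus: one dollar per completed set of 20 cumulated points."""
    if points_total < 0:
        raise ValueError("points must be non-negative")
    return int(points_total // 20)
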