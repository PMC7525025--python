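"""Spearman correlation stage: digital features vs clinical scores.

Emits the standard 5 x 4 matrix — rows BNSS apathy index, BNSS diminished
expression, BNSS total, PANSS NSFS, PANSS PSFS; columns high-effort
choice, activity ratio, gesture power, gesture count — with per-cell
listwise n, rank correlation and two-sided p.  Significance is the
per-cell p < 0.05 convention; an optional Benjamini-Hochberg correction is
available but off by default.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

SCORE_ROWS: tuple[str, ...] = ("bnss_apathy", "bnss_dimexp", "bnss_total", "panss_nsfs", "panss_psfs")
FEATURE_COLUMNS: tuple[str, ...] = (
    "high_effort_pct",
    "activity_time_ratio",
    "gesture_power_agg",
    "median_daily_gesture_count",
)

EXACT_P_MAX_N = 9


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    feature_name: str
    score_name: str
    n_pairs: int
    spearman_r: float
    p_value: float
    significant: bool


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p over all permutations of one rank vector."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rxc**2) * np.sum(ryc**2)))
    if denom == 0:
        return 1.0
    r_all = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def spearman_with_p(
    x: np.ndarray, y: np.ndarray, feature_name: str = "x", score_name: str = "y", alpha: float = 0.05
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value are excluded listwise.  p is two-sided: the
    t approximation for n > 9, an exact permutation test otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    r, p = sps.spearmanr(x, y)
    r = float(r)
    if n <= EXACT_P_MAX_N:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        p = _exact_permutation_p(rx, ry, r)
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return CorrelationResult(feature_name, score_name, int(n), r, p, p < alpha)


def correlation_table(
    cohort: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    scores: tuple[str, ...] = SCORE_ROWS,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """All feature x score Spearman correlations on a cohort table.

    Returns a long-form frame (one row per cell) with columns
    ``score``, ``feature``, ``n``, ``spearman_r``, ``p_value``,
    ``significant``.  Cells with fewer than 4 complete pairs carry NaN
    statistics.  With ``bh_correction`` the significance flag uses the
    Benjamini-Hochberg step-up over all computed cells instead of raw p.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    rows = []
    for score in scores:
        for feat in features:
            try:
                res = spearman_with_p(cohort[feat], cohort[score], feat, score, alpha)
                rows.append(
                    (score, feat, res.n_pairs, res.spearman_r, res.p_value, res.significant)
                )
            except InsufficientDataError:
                n_ok = int((np.isfinite(cohort[feat]) & np.isfinite(cohort[score])).sum())
                rows.append((score, feat, n_ok, math.nan, math.nan, False))
    out = pd.DataFrame(
        rows, columns=["score", "feature", "n", "spearman_r", "p_value", "significant"]
    )
    if bh_correction:
        out["significant"] = _benjamini_hochberg(out["p_value"].to_numpy(), alpha)
    return out


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    ok = np.isfinite(p)
    flags = np.zeros(p.size, dtype=bool)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return flags
    order = np.argsort(pv)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = pv[order] <= thresh
    k = np.nonzero(passed)[0]
    if k.size:
        cutoff = pv[order][k.max()]
        flags[ok] = p[ok] <= cutoff
    return flags


def to_matrix(table: pd.DataFrame, value: str = "spearman_r") -> pd.DataFrame:
    """Pivot the long-form table into the 5 x 4 matrix layout."""
    return table.pivot(index="score", columns="feature", values=value).reindex(
        index=list(SCORE_ROWS), columns=list(FEATURE_COLUMNS)
    )
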