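"""Session-level statistics: paired t-tests and Spearman rank trends.

Small-sample conventions used throughout the package: paired t-tests are
reported with two-sided p-values and no multiple-testing correction (the
Bonferroni threshold for a family of eight individual tests, p < 0.0063,
is exposed as a constant for reporting alongside raw p-values);
zero-variance difference vectors are flagged as degenerate rather than
yielding infinite statistics. Spearman trends across sessions use midranks
for ties, with an exact permutation p-value for n <= 9 tie-free samples
and the t-approximation otherwise.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

#: Bonferroni-corrected 5% threshold for the family of eight individual
#: static-hold tests (two directions x four participants).
BONFERRONI_8 = 0.05 / 8


@dataclass
class PairedComparison:
    """Classical paired t-test result on pre/post vectors."""

    n: int
    df: int
    mean_diff: float     # mean(post - pre)
    t: float
    p: float
    degenerate: bool     # True when the differences have zero variance

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < 0.05


def paired_t(pre: np.ndarray, post: np.ndarray) -> PairedComparison:
    """Two-sided paired t-test of post vs pre.

    Zero-variance differences are degenerate: t = 0 / p = 1 when the
    vectors are identical, undefined (NaN) otherwise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    d = post - pre
    mean_d = float(np.mean(d))
    # zero-variance detection up to float rounding of the subtraction
    if np.std(d, ddof=1) <= 1e-12 * max(1.0, abs(mean_d), float(np.max(np.abs(d)))):
        if mean_d == 0.0:
            return PairedComparison(n, n - 1, 0.0, 0.0, 1.0, degenerate=True)
        return PairedComparison(n, n - 1, mean_d, float("nan"), float("nan"), degenerate=True)
    res = spstats.ttest_rel(post, pre)
    return PairedComparison(n, n - 1, mean_d, float(res.statistic), float(res.pvalue), False)


@dataclass
class TrendResult:
    """Spearman rank correlation of a metric against session order."""

    n: int
    rho: float
    p: float
    tied: bool     # True when the metric is constant (rho undefined)
    exact: bool    # exact permutation p (n <= 9, no ties) vs t-approximation


@functools.lru_cache(maxsize=None)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)))
    d2 = np.sum((perms - base) ** 2, axis=1)
    rho = 1 - 6 * d2 / (n * (n**2 - 1))
    return np.sort(np.abs(rho))


def _exact_spearman_p(values: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for tie-free values vs 1..n."""
    n = len(values)
    ranks = spstats.rankdata(values)
    base = np.arange(1, n + 1)
    d2_obs = float(np.sum((ranks - base) ** 2))
    rho_obs = 1 - 6 * d2_obs / (n * (n**2 - 1))
    null = _exact_rho_null(n)
    p = 1.0 - np.searchsorted(null, abs(rho_obs) - 1e-12, side="left") / len(null)
    return rho_obs, float(p)


def spearman_trend(values: np.ndarray, session_index: np.ndarray | None = None) -> TrendResult:
    """Monotone-trend test of a per-session metric across ordered sessions."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("trend test needs >= 3 sessions")
    if session_index is None:
        session_index = np.arange(1, n + 1)
    session_index = np.asarray(session_index, dtype=float)
    order = np.argsort(session_index)
    values = values[order]

    if np.all(values == values[0]):
        return TrendResult(n, float("nan"), float("nan"), tied=True, exact=False)

    has_ties = len(np.unique(values)) < n
    if n <= 9 and not has_ties:
        rho, p = _exact_spearman_p(values)
        return TrendResult(n, float(rho), p, tied=False, exact=True)
    res = spstats.spearmanr(np.arange(1, n + 1), values)
    return TrendResult(n, float(res.statistic), float(res.pvalue), tied=False, exact=False)


AMPLITUDE_METRICS = ("mean_extensor", "mean_flexor")
TREND_METRICS = ("mean_er", "mean_extensor", "mean_flexor", "percent_success", "mean_threshold")


def session_metric_table(
    sessions: "list[list]",
    session_index: list[int] | None = None,
) -> pd.DataFrame:
    """Tidy per-session training metrics with trend statistics, one participant.

    ``sessions`` is an ordered list of per-session trial-result lists (the
    ``trials`` of :class:`myocoh.feedback.SessionResult`). Amplitude
    metrics (extensor, flexor) are Z-scored against the first listed
    session's per-trial mean and SD, so the first session sits at 0 by
    construction and later sessions are in first-session SD units. A
    Spearman trend across sessions is attached per metric.
    """
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions for a session table")
    if session_index is None:
        session_index = list(range(1, len(sessions) + 1))

    rows = []
    for idx, trials in zip(session_index, sessions):
        ers = [t.mean_er for t in trials if not np.isnan(t.mean_er)]
        rows.append(
            {
                "session": idx,
                "n_trials": len(trials),
                "mean_er": float(np.mean(ers)) if ers else float("nan"),
                "mean_extensor": float(np.mean([t.mean_extensor for t in trials])),
                "mean_flexor": float(np.mean([t.mean_flexor for t in trials])),
                "percent_success": 100.0 * float(np.mean([t.success for t in trials])),
                "mean_threshold": float(np.mean([t.er_threshold_used for t in trials])),
            }
        )
    table = pd.DataFrame(rows).set_index("session")

    # reference-session Z-score for amplitude metrics (first listed session)
    ref_trials = sessions[0]
    for metric, attr in (("mean_extensor", "mean_extensor"), ("mean_flexor", "mean_flexor")):
        per_trial = np.array([getattr(t, attr) for t in ref_trials], dtype=float)
        mu, sd = float(np.mean(per_trial)), float(np.std(per_trial, ddof=1))
        if sd > 0:
            table[metric + "_z"] = (table[metric] - mu) / sd

    if len(table) >= 3:
        trend_rows = {}
        for metric in TREND_METRICS:
            vals = table[metric].to_numpy()
            if np.any(np.isnan(vals)):
                continue
            tr = spearman_trend(vals, np.asarray(session_index))
            trend_rows[metric] = (tr.rho, tr.p)
        table.attrs["trends"] = trend_rows
    return table


def group_first_vs_last(tables: list[pd.DataFrame], metric: str) -> PairedComparison:
    """First-vs-last-session paired t across participants for one metric."""
    if len(tables) < 2:
        raise ValueError("group comparison needs >= 2 participants")
    first = np.array([t[metric].iloc[0] for t in tables])
    last = np.array([t[metric].iloc[-1] for t in tables])
    return paired_t(first, last)
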