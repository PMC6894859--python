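"""Interval behavior scoring: aggregation and Fisher's exact window tests.

Worms observed in chemical baths are scored by two blind reviewers over
six 15-s intervals covering the first 90 s.  Each worm-interval gets one
label: ``S`` (scrunched at least once), ``R`` (a non-scrunching reaction
such as head shaking), or ``N`` (no reaction — unhindered gliding).
Per-interval percentages are averaged across reviewers within each
replicate and then summarized as mean ± SD across replicates.

Latency-to-scrunch comparisons between two conditions use Fisher's exact
test on a 2×2 table of outcome-positive versus -negative worms in an
early window (the 15–30 s or 31–45 s interval).  Reviewer-averaged worm
counts can be half-integers; they are rounded (half-up by default, also
floor/ceil) to integers before the exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCORE_COLUMNS",
    "LABELS",
    "AggregateCurve",
    "WindowTest",
    "FisherResult",
    "validate_score_table",
    "aggregate",
    "fisher_exact",
    "compare_windows",
    "latency_summary",
]

SCORE_COLUMNS = ["condition", "replicate", "reviewer", "worm", "interval", "label"]
LABELS = ("S", "R", "N")
N_INTERVALS = 6
#: printed window names → interval index; "16–30" appears as a synonym of 15–30
WINDOW_ALIASES = {"15-30": 2, "16-30": 2, "31-45": 3}


def validate_score_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    intervals = df["interval"].astype(int)
    if intervals.min() < 1 or intervals.max() > N_INTERVALS:
        raise ValueError(f"interval indices must lie in 1..{N_INTERVALS}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}; expected {LABELS}")
    key = ["condition", "replicate", "reviewer", "worm", "interval"]
    if df.duplicated(subset=key).any():
        raise ValueError("duplicate (condition, replicate, reviewer, worm, interval) rows")
    return df


@dataclass
class AggregateCurve:
    """Per-interval percentages, averaged over reviewers then replicates."""

    intervals: np.ndarray
    pct_scrunching_mean: np.ndarray
    pct_scrunching_sd: np.ndarray
    pct_reacting_mean: np.ndarray
    pct_reacting_sd: np.ndarray
    n_replicates: int
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "interval": self.intervals,
            "pct_scrunching_mean": self.pct_scrunching_mean,
            "pct_scrunching_sd": self.pct_scrunching_sd,
            "pct_reacting_mean": self.pct_reacting_mean,
            "pct_reacting_sd": self.pct_reacting_sd,
        })


def aggregate(df: pd.DataFrame, condition: str) -> AggregateCurve:
    """Mean ± SD (ddof=1, across replicates) of the percentage of worms
    scrunching and reacting, per 15-s interval."""
    validate_score_table(df)
    sub = df[df["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no records for condition {condition!r}")

    per_rep_scr, per_rep_rea = [], []
    for rep, grp in sub.groupby("replicate"):
        reviewers = sorted(grp["reviewer"].unique())
        scr_rows, rea_rows = [], []
        for rev in reviewers:
            g = grp[grp["reviewer"] == rev]
            have = set(g["interval"].astype(int))
            gaps = set(range(1, N_INTERVALS + 1)) - have
            if gaps:
                raise ValueError(
                    f"condition {condition!r} replicate {rep} reviewer {rev} "
                    f"missing intervals {sorted(gaps)}")
            n_worms = g["worm"].nunique()
            counts = g.pivot_table(index="interval", columns="label", values="worm",
                                   aggfunc="count", fill_value=0)
            s = counts.get("S", pd.Series(0, index=counts.index))
            r = counts.get("R", pd.Series(0, index=counts.index))
            scr_rows.append(100.0 * s.reindex(range(1, N_INTERVALS + 1), fill_value=0)
                            .to_numpy() / n_worms)
            rea_rows.append(100.0 * (s + r).reindex(range(1, N_INTERVALS + 1), fill_value=0)
                            .to_numpy() / n_worms)
        per_rep_scr.append(np.mean(scr_rows, axis=0))
        per_rep_rea.append(np.mean(rea_rows, axis=0))

    scr = np.asarray(per_rep_scr)
    rea = np.asarray(per_rep_rea)
    n_rep = scr.shape[0]
    sd = (lambda a: a.std(axis=0, ddof=1)) if n_rep > 1 else (lambda a: np.zeros(a.shape[1]))
    return AggregateCurve(intervals=np.arange(1, N_INTERVALS + 1),
                          pct_scrunching_mean=scr.mean(axis=0), pct_scrunching_sd=sd(scr),
                          pct_reacting_mean=rea.mean(axis=0), pct_reacting_sd=sd(rea),
                          n_replicates=n_rep, condition=condition)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # nan when 0/0
    p_value: float
    degenerate: bool = False


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2×2 table of counts.

    The p-value sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed one.  A
    zero margin makes every table equally likely: p = 1, flagged
    degenerate.  The odds ratio is (a·d)/(b·c), NaN for 0/0.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    num, den = a * d, b * c
    odds = np.nan if num == 0 and den == 0 else (np.inf if den == 0 else num / den)
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        return FisherResult(odds_ratio=odds, p_value=1.0, degenerate=True)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(odds_ratio=odds, p_value=float(p))


def _round_counts(x: float, mode: str) -> int:
    if mode == "half_up":
        return int(math.floor(x + 0.5))
    if mode == "floor":
        return int(math.floor(x))
    if mode == "ceil":
        return int(math.ceil(x))
    raise ValueError(f"unknown rounding mode {mode!r}")


@dataclass
class WindowTest:
    window: tuple[int, ...]       # interval indices
    outcome: str                  # "scrunch" or "react"
    counts: np.ndarray            # 2x2: [condition A, condition B] x [positive, negative]
    odds_ratio: float
    p_value: float
    conditions: tuple[str, str] = ("A", "B")


def _window_intervals(window) -> tuple[int, ...]:
    if isinstance(window, str):
        if window not in WINDOW_ALIASES:
            raise ValueError(f"unknown window {window!r}; known: {sorted(WINDOW_ALIASES)}")
        return (WINDOW_ALIASES[window],)
    if isinstance(window, int):
        window = (window,)
    window = tuple(int(w) for w in window)
    if any(w < 1 or w > N_INTERVALS for w in window):
        raise ValueError("window intervals must lie in 1..6")
    return window


def _positive_count(sub: pd.DataFrame, intervals, outcome_labels, rounding: str) -> tuple[int, int]:
    """Summed (positives, total) over replicates, reviewer-averaged."""
    pos = total = 0
    for _, grp in sub.groupby("replicate"):
        counts = []
        n_worms = grp["worm"].nunique()
        for _, g in grp.groupby("reviewer"):
            in_win = g[g["interval"].astype(int).isin(intervals)]
            hit = in_win[in_win["label"].isin(outcome_labels)]["worm"].nunique()
            counts.append(hit)
        pos += _round_counts(float(np.mean(counts)), rounding)
        total += n_worms
    return pos, total


def compare_windows(df: pd.DataFrame, condition_a: str, condition_b: str,
                    window="15-30", outcome: str = "scrunch",
                    rounding: str = "half_up") -> WindowTest:
    """Fisher's exact comparison of two conditions in an early window.

    A worm is outcome-positive if at least one of its labels in the
    window intervals is in the outcome set (``scrunch`` → {S},
    ``react`` → {S, R}) — counted per reviewer, averaged across the two
    reviewers, rounded, and summed over replicates.
    """
    validate_score_table(df)
    intervals = _window_intervals(window)
    if outcome == "scrunch":
        labels = {"S"}
    elif outcome == "react":
        labels = {"S", "R"}
    else:
        raise ValueError("outcome must be 'scrunch' or 'react'")

    table = []
    for cond in (condition_a, condition_b):
        sub = df[df["condition"] == cond]
        if sub.empty:
            raise ValueError(f"no records for condition {cond!r}")
        pos, total = _positive_count(sub, intervals, labels, rounding)
        table.append([pos, total - pos])
    counts = np.asarray(table, dtype=int)
    res = fisher_exact(counts)
    return WindowTest(window=intervals, outcome=outcome, counts=counts,
                      odds_ratio=res.odds_ratio, p_value=res.p_value,
                      conditions=(condition_a, condition_b))


def latency_summary(curve: AggregateCurve, threshold_pct: float):
    """First 1-based interval where the scrunching percentage reaches the
    threshold, or None if it never does."""
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    hits = np.flatnonzero(curve.pct_scrunching_mean >= threshold_pct)
    return int(curve.intervals[hits[0]]) if len(hits) else None
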