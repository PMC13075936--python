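"""Behavioral endpoints of the rGT.

Percent choice, the decision score [(P1+P2) - (P3+P4)], risk-status
classification, premature responding, the arcsine transform applied to
percentage variables, stable-baseline window selection, devaluation
shift scores, and the one-way ANOVA + Tukey HSD used to compare decision
scores across task variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import OPTIONS

__all__ = [
    "BehaviorSummary",
    "choice_percentages",
    "decision_score",
    "classify_risk_status",
    "premature_rate",
    "arcsine_transform",
    "stable_window",
    "devaluation_shift",
    "one_way_anova",
    "tukey_hsd",
    "summarize_subjects",
]


@dataclass
class BehaviorSummary:
    """Per-subject behavioral summary over a session window."""

    subject_id: str
    session_window: tuple
    pct_choice: np.ndarray  # length 4, sums to 100
    decision_score: float
    risk_status: str
    premature_pct: float
    trials_completed: int
    omissions: int
    latency_choice_s: float = np.nan
    latency_collect_s: float = np.nan


def _window_mask(df: pd.DataFrame, window: Optional[tuple]) -> pd.Series:
    if window is None:
        return pd.Series(True, index=df.index)
    lo, hi = window
    return (df["session"] >= lo) & (df["session"] <= hi)


def choice_percentages(trials: pd.DataFrame, window: Optional[tuple] = None) -> np.ndarray:
    """Percent choice of each option: times chosen / total choices x 100.

    Premature and omitted trials are excluded from the denominator.
    """
    df = trials[_window_mask(trials, window)]
    valid = df[df["outcome"].isin(["win", "loss"])]
    if len(valid) == 0:
        raise ValueError("no valid choices in window")
    counts = valid["choice"].value_counts()
    pct = np.array([counts.get(o, 0) for o in OPTIONS], dtype=float)
    return pct / pct.sum() * 100.0


def decision_score(pct: Sequence[float]) -> float:
    """Decision score (P1% + P2%) - (P3% + P4%); positive = optimal."""
    pct = np.asarray(pct, dtype=float)
    if pct.shape != (4,) or not np.isclose(pct.sum(), 100.0):
        raise ValueError("pct must be a 4-vector summing to 100")
    score = (pct[0] + pct[1]) - (pct[2] + pct[3])
    return float(np.clip(score, -100.0, 100.0))  # guard rounding at the rails


def classify_risk_status(score: float) -> str:
    """Positive scores are 'optimal', negative 'risk_preferring'.

    A score of exactly zero is classified optimal (documented boundary
    convention for a measure-zero case).
    """
    if not -100.0 <= score <= 100.0:
        raise ValueError("score must be in [-100, 100]")
    return "optimal" if score >= 0 else "risk_preferring"


def premature_rate(trials: pd.DataFrame, window: Optional[tuple] = None) -> float:
    """Premature responses / trials initiated x 100.

    The denominator counts every initiated trial: valid choices,
    premature responses, and omissions.
    """
    df = trials[_window_mask(trials, window)]
    if len(df) == 0:
        raise ValueError("no initiated trials in window")
    return float((df["outcome"] == "premature").mean() * 100.0)


def arcsine_transform(percent) -> np.ndarray | float:
    """asin(sqrt(p/100)): variance-stabilizing transform for percentages."""
    p = np.asarray(percent, dtype=float)
    if np.any(p < 0) or np.any(p > 100):
        raise ValueError("percent must be in [0, 100]")
    out = np.arcsin(np.sqrt(p / 100.0))
    return float(out) if out.ndim == 0 else out


def _window_is_stable(scores: np.ndarray, alpha: float) -> bool:
    """No significant session effect within the window.

    2-D input (subjects x sessions): one-way ANOVA with sessions as
    groups.  1-D input: t-test on the within-window linear trend, with
    degenerate (zero-residual) windows stable iff the trend is flat.
    """
    if scores.ndim == 2:
        cols = [scores[:, j] for j in range(scores.shape[1])]
        if all(np.ptp(c) == 0 for c in cols) and len({c[0] for c in cols}) == 1:
            return True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*cols)
        return bool(np.isnan(p) or p > alpha)
    x = np.arange(scores.size)
    if np.ptp(scores) == 0:
        return True
    res = stats.linregress(x, scores)
    if np.isnan(res.pvalue):  # perfect fit: stable only if flat
        return res.slope == 0
    return bool(res.pvalue > alpha)


def stable_window(
    session_scores, k: int = 4, alpha: float = 0.05
) -> tuple[int, int]:
    """Latest k-session window with no significant session effect.

    ``session_scores`` is a 1-D array of per-session scores or a 2-D
    (subjects x sessions) matrix.  Returns 1-based inclusive session
    indices ``(start, end)``.  If no window is stable, the last k
    sessions are returned with a warning.
    """
    scores = np.asarray(session_scores, dtype=float)
    n = scores.shape[-1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} sessions, got {n}")
    for start in range(n - k, -1, -1):
        win = scores[..., start : start + k]
        if _window_is_stable(win, alpha):
            return (start + 1, start + k)
    warnings.warn(
        "no statistically stable window found; falling back to the last "
        f"{k} sessions",
        RuntimeWarning,
    )
    return (n - k + 1, n)


def devaluation_shift(
    baseline: BehaviorSummary, devalued: BehaviorSummary
) -> tuple[np.ndarray, float]:
    """Per-option change in % choice and decision-score change.

    Computed as devaluation minus baseline; the per-option deltas sum to
    zero because both inputs sum to 100.
    """
    if baseline.subject_id != devalued.subject_id:
        raise ValueError("baseline and devalued summaries must share a subject")
    delta = np.asarray(devalued.pct_choice, float) - np.asarray(baseline.pct_choice, float)
    return delta, devalued.decision_score - baseline.decision_score


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    k = len(groups)
    n = sum(len(g) for g in groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # identical groups: zero between- and within-variance
        f, p = 0.0, 1.0
    return float(f), k - 1, n - k, float(p)


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons.

    Returns a tidy frame with one row per (group_a, group_b) pair,
    ``mean_difference`` oriented as group_a minus group_b, and the
    studentized-range adjusted p-value.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(g) < 2 for g in arrs):
        raise ValueError("need >=2 groups with >=2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    res = stats.tukey_hsd(*arrs)
    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_difference": float(np.mean(arrs[i]) - np.mean(arrs[j])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def summarize_subjects(
    logs: pd.DataFrame, window: Optional[tuple] = None
) -> pd.DataFrame:
    """Tidy per-subject behavioral summary over a session window."""
    rows = []
    for sid, sub in logs.groupby("subject_id"):
        pct = choice_percentages(sub, window)
        score = decision_score(pct)
        df = sub[_window_mask(sub, window)]
        rows.append(
            {
                "subject_id": sid,
                "window_start": window[0] if window else int(df["session"].min()),
                "window_end": window[1] if window else int(df["session"].max()),
                **{f"pct_{o}": pct[i] for i, o in enumerate(OPTIONS)},
                "decision_score": score,
                "risk_status": classify_risk_status(score),
                "premature_pct": premature_rate(sub, window),
                "trials_completed": int(df["outcome"].isin(["win", "loss"]).sum()),
                "omissions": int((df["outcome"] == "omission").sum()),
            }
        )
    return pd.DataFrame(rows)
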