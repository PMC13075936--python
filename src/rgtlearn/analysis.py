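"""Posterior analysis: HDI contrasts, forward simulation, regressions.

Group-level parameter differences are assessed by the highest-density
interval of the difference of group means (credible when the 95% HDI
excludes zero); fitted subject-level estimates are pushed forward
through the task simulator to check that the models reproduce long-run
risk preference; and subject-level estimates are regressed on final
decision scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics, task
from .inference import PosteriorFit
from .models import RLParams, SimulationResult, simulate_agent

__all__ = [
    "hdi",
    "ContrastResult",
    "group_contrast",
    "CohortSimulation",
    "forward_simulate_cohort",
    "simulated_decision_scores",
    "RegressionResult",
    "regress_param_vs_score",
]


def hdi(samples: Sequence[float], prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` posterior mass.

    Sorted-window algorithm: over all windows of ceil(prob*n) consecutive
    order statistics, return the narrowest.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an HDI")
    if not 0.0 < prob <= 1.0:
        raise ValueError("prob must be in (0, 1]")
    m = int(np.ceil(prob * n))  # points inside the window
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class ContrastResult:
    """Posterior contrast of one group-level parameter between two fits."""

    parameter: str
    group_pair: tuple
    samples: np.ndarray  # difference of group means, a - b
    hdi_low: float
    hdi_high: float
    credible: bool

    def __post_init__(self) -> None:
        assert self.hdi_low <= self.hdi_high
        assert self.credible == (not self.hdi_low <= 0.0 <= self.hdi_high)


def group_contrast(
    fit_a: PosteriorFit,
    fit_b: PosteriorFit,
    parameter: str,
    prob: float = 0.95,
    labels: tuple = ("a", "b"),
    seed: int = 0,
) -> ContrastResult:
    """HDI contrast of a group-mean parameter on the constrained scale.

    The difference distribution is fit_a minus fit_b.  When the two fits
    carry unequal sample counts the larger is subsampled without
    replacement (seeded) to pair the draws.
    """
    for f in (fit_a, fit_b):
        if parameter not in f.param_names:
            raise KeyError(f"parameter {parameter!r} absent from {f.model_id} fit")
    a = fit_a.group_mean_samples(parameter)
    b = fit_b.group_mean_samples(parameter)
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        m = min(a.size, b.size)
        if a.size > m:
            a = rng.choice(a, size=m, replace=False)
        else:
            b = rng.choice(b, size=m, replace=False)
    diff = a - b
    lo, hi = hdi(diff, prob)
    return ContrastResult(
        parameter=parameter,
        group_pair=labels,
        samples=diff,
        hdi_low=lo,
        hdi_high=hi,
        credible=not lo <= 0.0 <= hi,
    )


@dataclass
class CohortSimulation:
    """Forward simulations of a cohort, one per subject."""

    subject_ids: list
    simulations: List[SimulationResult]
    n_sessions: int
    trials_mode: str


def forward_simulate_cohort(
    subject_params: Sequence[RLParams],
    subject_ids: Optional[Sequence[str]] = None,
    n_sessions: int = 40,
    trials_mode: str = "time_budget",
    seed: int = 0,
    schedule_set=None,
    trials_per_session: int = 120,
    session_config: Optional[task.SessionConfig] = None,
) -> CohortSimulation:
    """Simulate each subject's fitted parameters for ``n_sessions``.

    Subject random streams are spawned from ``seed``, so output is
    byte-identical under the same seed and parameters.
    """
    if len(subject_params) == 0:
        raise ValueError("empty subject list")
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(len(subject_params))]
    sims = []
    for p, ss in zip(subject_params, np.random.SeedSequence(seed).spawn(len(subject_params))):
        sims.append(
            simulate_agent(
                p,
                schedule_set=schedule_set,
                n_sessions=n_sessions,
                trials_mode=trials_mode,
                rng=np.random.default_rng(ss),
                trials_per_session=trials_per_session,
                session_config=session_config,
            )
        )
    return CohortSimulation(
        subject_ids=list(subject_ids),
        simulations=sims,
        n_sessions=n_sessions,
        trials_mode=trials_mode,
    )


def simulated_decision_scores(
    sim: CohortSimulation,
    session_window: tuple = (36, 40),
    mode: str = "probability",
) -> pd.Series:
    """Per-subject decision score over a simulated session window.

    ``mode="probability"`` scores the mean per-trial choice probabilities
    (variance-reduced); ``mode="sampled"`` scores the realized choices.
    """
    lo, hi = session_window
    if lo < 1 or hi > sim.n_sessions:
        raise ValueError(
            f"window {session_window} outside simulated range 1..{sim.n_sessions}"
        )
    scores = {}
    for sid, s in zip(sim.subject_ids, sim.simulations):
        mask = (s.sessions >= lo) & (s.sessions <= hi)
        if mode == "probability":
            pct = s.probs[mask].mean(axis=0) * 100.0
        elif mode == "sampled":
            counts = np.bincount(s.choices[mask], minlength=4).astype(float)
            pct = counts / counts.sum() * 100.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        scores[sid] = metrics.decision_score(pct)
    return pd.Series(scores, name="decision_score")


@dataclass
class RegressionResult:
    """Simple OLS of final decision score on one parameter estimate."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple
    p_value: float
    n: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.r_squared <= 1.0 + 1e-12
        assert self.f_stat >= 0.0


def regress_param_vs_score(param_estimates, final_scores) -> RegressionResult:
    """OLS slope test: F = t^2 on (1, n-2) degrees of freedom."""
    x = np.asarray(param_estimates, dtype=float)
    y = np.asarray(final_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("param_estimates and final_scores must be paired vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    df = (1, n - 2)
    if np.isclose(r2, 1.0):
        f = np.inf
        p = 0.0
    else:
        f = r2 / (1.0 - r2) * df[1]
        p = float(stats.f.sf(f, *df))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        f_stat=float(f),
        df=df,
        p_value=p,
        n=n,
    )
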