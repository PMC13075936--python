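"""Synthetic cohorts of RL agents playing the rGT.

Emulates the statistical structure of a multi-cohort rGT experiment:
groups of subjects whose model parameters are drawn from group-level
distributions on the unconstrained scale (the same scale and constraint
transforms the hierarchical inference uses), each agent then playing the
reinforcement schedules for a number of 30-minute sessions.  Group
differences are injected through the punishment learning rate and the
offset b by default, the parameters that separate task variants in real
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

from . import task
from .models import MODEL_PARAMS, QAgentPolicy, RLParams
from ._kernels import MODEL_CODES, MODEL_TRANSFORMS

__all__ = [
    "GroupHyperParams",
    "SyntheticCohort",
    "default_hypers",
    "sample_cohort_params",
    "generate_cohort_logs",
    "make_two_group_experiment",
    "VARIANT_ETA_MINUS",
]


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level means and SDs on the unconstrained scale.

    ``mu`` and ``sd`` are keyed by parameter name (beta, eta_plus,
    eta_minus, and the model-specific subset).  Learning-rate means are
    most conveniently set as ``ndtri(target_rate)``.
    """

    model_id: str
    n_subjects: int
    mu: Dict[str, float]
    sd: Dict[str, float]
    task_variant: str = "uncued"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        names = MODEL_PARAMS[self.model_id]
        missing = set(names) - set(self.mu) | set(names) - set(self.sd)
        if missing:
            raise ValueError(f"missing hyperparameters for {sorted(missing)}")
        for n, s in self.sd.items():
            if s <= 0:
                raise ValueError(f"SD for {n} must be > 0")


@dataclass
class SyntheticCohort:
    """True generating parameters plus the trial logs they produced."""

    hyper: GroupHyperParams
    true_params: List[RLParams]
    logs: pd.DataFrame
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        """Per-subject true parameters (sidecar for recovery tests)."""
        names = MODEL_PARAMS[self.hyper.model_id]
        rows = [
            dict(subject_id=sid, **{n: getattr(p, n) for n in names})
            for sid, p in zip(sorted(self.logs["subject_id"].unique()), self.true_params)
        ]
        return pd.DataFrame(rows)


#: order-of-magnitude default hypers shared across groups (unconstrained scale)
_BASE_MU = {
    "beta": float(np.log(1.5)),
    "eta_plus": float(ndtri(0.12)),
    "eta_minus": float(ndtri(0.25)),
    "m": float(np.log(0.05)),
    "b": 0.5,
    "r": float(np.log(0.35)),
    "m_rew": 0.0,
}
_BASE_SD = {
    "beta": 0.3,
    "eta_plus": 0.25,
    "eta_minus": 0.25,
    "m": 0.3,
    "b": 0.5,
    "r": 0.2,
    "m_rew": 0.2,
}

#: per-task-variant punishment learning rates (constrained scale) whose rank
#: order mirrors the decision-score ordering across cue variants: the
#: loss-cued task learns most from losses, win-paired-cue tasks least.
VARIANT_ETA_MINUS = {
    "loss": 0.45,
    "uncued": 0.30,
    "random50": 0.28,
    "reverse": 0.18,
    "standard": 0.12,
    "outcome": 0.12,
}


def default_hypers(
    model_id: str = "nonlinear",
    task_variant: str = "uncued",
    n_subjects: int = 28,
    eta_minus: Optional[float] = None,
    b_mu: Optional[float] = None,
) -> GroupHyperParams:
    """Default group hypers for one task variant.

    ``eta_minus`` (constrained scale) overrides the variant's default
    punishment learning rate; ``b_mu`` overrides the offset mean.
    """
    names = MODEL_PARAMS[model_id]
    mu = {n: _BASE_MU[n] for n in names}
    sd = {n: _BASE_SD[n] for n in names}
    em = eta_minus if eta_minus is not None else VARIANT_ETA_MINUS[task_variant]
    mu["eta_minus"] = float(ndtri(em))
    if b_mu is not None and "b" in names:
        mu["b"] = float(b_mu)
    return GroupHyperParams(
        model_id=model_id, n_subjects=n_subjects, mu=mu, sd=sd, task_variant=task_variant
    )


def _constrain(name: str, model_id: str, u: np.ndarray) -> np.ndarray:
    names = MODEL_PARAMS[model_id]
    code = MODEL_CODES[model_id]
    tc = MODEL_TRANSFORMS[code, names.index(name)]
    if tc == 0:
        return np.exp(u)
    if tc == 1:
        return norm.cdf(u)
    return u


def sample_cohort_params(
    hyper: GroupHyperParams, seed: int | np.random.SeedSequence = 0
) -> List[RLParams]:
    """Draw one parameter set per subject.

    Draws are Normal(mu, sd) on the unconstrained scale, then mapped
    through the same constraint transforms used by inference.
    """
    rng = np.random.default_rng(seed)
    names = MODEL_PARAMS[hyper.model_id]
    out = []
    for _ in range(hyper.n_subjects):
        vals = {}
        for n in names:
            u = hyper.mu[n] + hyper.sd[n] * rng.standard_normal()
            vals[n] = float(_constrain(n, hyper.model_id, np.array(u)))
        out.append(RLParams(model_id=hyper.model_id, **vals))
    return out


def generate_cohort_logs(
    params: Sequence[RLParams],
    n_sessions: int = 5,
    config: Optional[task.SessionConfig] = None,
    seed: int = 0,
    schedule_set: Optional[Sequence[task.OptionSchedule]] = None,
    subject_prefix: str = "S",
    task_variant: str = "uncued",
) -> pd.DataFrame:
    """Play each agent through ``n_sessions`` time-budget sessions.

    Q starts at zero and carries across a subject's sessions.  Subject
    random streams are spawned from one master seed, so any subject's log
    is reproducible independently of cohort size.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if config is None:
        config = task.SessionConfig(cue_variant=task_variant if task_variant in task.CUE_VARIANTS else "uncued")
    if schedule_set is None:
        schedule_set = task.default_schedule()
    streams = np.random.SeedSequence(seed).spawn(len(params))
    rows = []
    for i, (p, ss) in enumerate(zip(params, streams)):
        rng = np.random.default_rng(ss)
        sid = f"{subject_prefix}{i:03d}"
        agent = QAgentPolicy(p, rng)
        for sess in range(1, n_sessions + 1):
            records = task.run_session(
                agent, schedule_set, config, rng, subject_id=sid, session=sess
            )
            agent.end_session(records)
            for rec in records:
                rows.append(
                    {
                        "subject_id": sid,
                        "task_variant": task_variant,
                        "session": rec.session,
                        "trial_index": rec.trial_index,
                        "choice": rec.choice if rec.choice is not None else "",
                        "outcome": rec.outcome,
                        "pellets": rec.pellets,
                        "penalty_s": rec.penalty_s,
                        "cue_played": int(rec.cue_played),
                        "premature": int(rec.outcome == "premature"),
                        "omission": int(rec.outcome == "omission"),
                        "latency_choice_s": rec.latency_choice_s,
                        "latency_collect_s": rec.latency_collect_s,
                    }
                )
    return pd.DataFrame(rows)


def make_cohort(
    hyper: GroupHyperParams,
    n_sessions: int = 5,
    seed: int = 0,
    config: Optional[task.SessionConfig] = None,
) -> SyntheticCohort:
    """Sample parameters and generate logs in one reproducible step."""
    root = np.random.SeedSequence(seed)
    par_seed, log_seed = root.spawn(2)
    params = sample_cohort_params(hyper, par_seed)
    logs = generate_cohort_logs(
        params,
        n_sessions=n_sessions,
        config=config,
        seed=int(log_seed.generate_state(1)[0] % (2**31)),
        task_variant=hyper.task_variant,
    )
    return SyntheticCohort(hyper=hyper, true_params=params, logs=logs, seed=seed)


def make_two_group_experiment(
    eta_minus: tuple[float, float] = (0.15, 0.45),
    n_subjects: int = 12,
    n_sessions: int = 5,
    model_id: str = "nonlinear",
    seed: int = 0,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two groups differing only in the group-mean punishment learning rate.

    The canonical desk-scale recovery experiment: a loss-insensitive
    group (low eta-) versus a loss-sensitive group (high eta-), all other
    hypers shared.
    """
    lo, hi = np.random.SeedSequence(seed).spawn(2)
    h_low = default_hypers(model_id, "uncued", n_subjects, eta_minus=eta_minus[0])
    h_high = default_hypers(model_id, "uncued", n_subjects, eta_minus=eta_minus[1])
    c_low = make_cohort(h_low, n_sessions, seed=int(lo.generate_state(1)[0] % (2**31)))
    c_high = make_cohort(h_high, n_sessions, seed=int(hi.generate_state(1)[0] % (2**31)))
    return c_low, c_high


def make_experiment(
    preset: str = "desk",
    model_id: str = "nonlinear",
    seed: int = 0,
) -> Dict[str, SyntheticCohort]:
    """Multi-variant synthetic experiment.

    ``preset="paper"``: six task variants x 28 subjects x 40 sessions.
    ``preset="desk"``: two variants (uncued, standard) x 12 subjects x 5
    sessions, sized for laptop-scale testing.
    """
    if preset == "paper":
        variants = list(VARIANT_ETA_MINUS)
        n_subjects, n_sessions = 28, 40
    elif preset == "desk":
        variants = ["uncued", "standard"]
        n_subjects, n_sessions = 12, 5
    else:
        raise ValueError(f"unknown preset {preset!r}")
    seqs = np.random.SeedSequence(seed).spawn(len(variants))
    out = {}
    for variant, ss in zip(variants, seqs):
        hyper = default_hypers(model_id, variant, n_subjects)
        out[variant] = make_cohort(
            hyper, n_sessions, seed=int(ss.generate_state(1)[0] % (2**31))
        )
    return out
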