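"""Q-learning models of trial-by-trial rGT choice.

Five models share a softmax decision rule over four latent Q-values (in
pellet-equivalent units) and a delta-rule update of the chosen option on
wins.  They differ in how a loss's time-out duration ``T`` (seconds) is
transformed into a pellet-equivalent cost that the punishment update
drives Q toward:

=============   ======  ===========================
model           params  loss target
=============   ======  ===========================
basic           3       0
scaled          4       -m*T
scaled_offset   5       b - m*T
nonlinear       5       b - T**r
reward_scaled   5       -m*T (win target mRew*R)
=============   ======  ===========================

Q-values start at zero on a subject's first trial and carry over across
session boundaries (no intersession forgetting).  Only the chosen
option's Q-value is ever updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import task
from ._kernels import (
    MODEL_CODES,
    MODEL_K,
    MODEL_PARAM_NAMES,
    MODEL_TRANSFORMS,
    _subject_ll_grad,
    _subject_pointwise,
)

__all__ = [
    "MODEL_IDS",
    "MODEL_PARAMS",
    "RLParams",
    "softmax_probs",
    "update_win",
    "update_loss",
    "subject_loglik",
    "simulate_agent",
    "SimulationResult",
    "QAgentPolicy",
    "trials_to_arrays",
]

MODEL_IDS = tuple(MODEL_CODES)

#: active parameter names per model id
MODEL_PARAMS = {mid: MODEL_PARAM_NAMES[code] for mid, code in MODEL_CODES.items()}

#: softmax exponent guard (overflow-free up to double range)
_CLIP = 700.0


@dataclass(frozen=True)
class RLParams:
    """One subject's model parameters on the constrained (natural) scale."""

    model_id: str
    beta: float
    eta_plus: float
    eta_minus: float
    m: Optional[float] = None
    b: Optional[float] = None
    r: Optional[float] = None
    m_rew: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_CODES:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        active = set(MODEL_PARAMS[self.model_id])
        for name in ("m", "b", "r", "m_rew"):
            val = getattr(self, name)
            if name in active and val is None:
                raise ValueError(f"{self.model_id} requires parameter {name!r}")
            if name not in active and val is not None:
                raise ValueError(f"{self.model_id} does not use parameter {name!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        for name in ("eta_plus", "eta_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_vector(self) -> np.ndarray:
        """Constrained parameter vector in the model's canonical order."""
        return np.array([getattr(self, n) for n in MODEL_PARAMS[self.model_id]], float)

    @classmethod
    def from_vector(cls, model_id: str, vec: Sequence[float]) -> "RLParams":
        names = MODEL_PARAMS[model_id]
        if len(vec) != len(names):
            raise ValueError(f"{model_id} expects {len(names)} parameters")
        return cls(model_id=model_id, **dict(zip(names, map(float, vec))))


def softmax_probs(q: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities p_x = exp(beta*Q_x) / sum_y exp(beta*Q_y)."""
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("Q-values must be finite")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    v = beta * q
    v = np.clip(v - v.max(), -_CLIP, 0.0)
    e = np.exp(v)
    return e / e.sum()


def _win_target(params: RLParams, r_tr: float) -> float:
    if params.model_id == "reward_scaled":
        return params.m_rew * r_tr
    return float(r_tr)


def _loss_target(params: RLParams, t_tr: float) -> float:
    mid = params.model_id
    if mid == "basic":
        return 0.0
    if mid in ("scaled", "reward_scaled"):
        return -params.m * t_tr
    if mid == "scaled_offset":
        return params.b - params.m * t_tr
    return params.b - t_tr ** params.r  # nonlinear


def update_win(q: np.ndarray, choice: int, r_tr: float, params: RLParams) -> np.ndarray:
    """Delta-rule update of the chosen option after a win of ``r_tr`` pellets."""
    if r_tr <= 0:
        raise ValueError("R_tr must be > 0 on a win")
    q = np.array(q, dtype=float)
    tgt = _win_target(params, r_tr)
    q[choice] += params.eta_plus * (tgt - q[choice])
    return q


def update_loss(q: np.ndarray, choice: int, t_tr: float, params: RLParams) -> np.ndarray:
    """Punishment update of the chosen option after a ``t_tr``-second time-out."""
    if t_tr < 0:
        raise ValueError("T_tr must be >= 0")
    q = np.array(q, dtype=float)
    tgt = _loss_target(params, t_tr)
    q[choice] += params.eta_minus * (tgt - q[choice])
    return q


def trials_to_arrays(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Convert a trial sequence to flat (choices, is_win, rewards, penalties).

    Accepts a DataFrame with columns (session, trial_index, choice,
    outcome, pellets, penalty_s) or a sequence of
    :class:`~rgtlearn.task.TrialRecord`.  Input must be sorted by
    (session, trial_index) and contain only valid win/loss trials.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        df = pd.DataFrame(
            {
                "session": [t.session for t in trials],
                "trial_index": [t.trial_index for t in trials],
                "choice": [t.choice for t in trials],
                "outcome": [t.outcome for t in trials],
                "pellets": [t.pellets for t in trials],
                "penalty_s": [t.penalty_s for t in trials],
            }
        )
    bad = ~df["outcome"].isin(["win", "loss"])
    if bad.any():
        raise ValueError(
            "trials must contain valid choices only (win/loss); found "
            f"{df.loc[bad, 'outcome'].unique().tolist()}"
        )
    key = df[["session", "trial_index"]].to_numpy()
    if len(key) > 1:
        order = np.lexsort((key[:, 1], key[:, 0]))
        if not np.array_equal(order, np.arange(len(key))):
            raise ValueError("trials must be sorted by (session, trial_index)")
    choices = df["choice"].map({o: i for i, o in enumerate(task.OPTIONS)}).to_numpy(np.int64)
    is_win = (df["outcome"] == "win").to_numpy(np.int64)
    rewards = df["pellets"].to_numpy(float)
    penalties = df["penalty_s"].to_numpy(float)
    return choices, is_win, rewards, penalties


def subject_loglik(params: RLParams, trials) -> tuple[float, np.ndarray]:
    """Sequential log-likelihood of one subject's valid choices.

    Iterates softmax -> log p(observed choice) -> delta-rule update, with
    Q persisting across session boundaries.  Returns the total and the
    pointwise log-likelihood vector (one entry per valid trial).
    """
    choices, is_win, rewards, penalties = trials_to_arrays(trials)
    code = MODEL_CODES[params.model_id]
    out = np.empty(len(choices))
    _subject_pointwise(params.to_vector(), code, choices, is_win, rewards, penalties, out)
    return float(out.sum()), out


def subject_loglik_grad(params: RLParams, trials) -> tuple[float, np.ndarray]:
    """Total log-likelihood and its gradient w.r.t. the constrained parameters."""
    choices, is_win, rewards, penalties = trials_to_arrays(trials)
    code = MODEL_CODES[params.model_id]
    K = int(MODEL_K[code])
    grad = np.empty(K)
    ll = _subject_ll_grad(
        params.to_vector(), K, code, choices, is_win, rewards, penalties, grad
    )
    return float(ll), grad


class QAgentPolicy:
    """Stateful softmax Q-learning policy usable with :func:`task.run_session`.

    The policy learns from the session history it is handed on each call,
    so premature/omitted trials (which carry no choice) are ignored.  Q
    persists across sessions; call :meth:`end_session` with the finished
    session's records so trailing outcomes are learned before the next
    session starts.
    """

    def __init__(self, params: RLParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.q = np.zeros(4)
        self._seen = 0
        self.prob_trace: List[np.ndarray] = []

    def _learn(self, records: Sequence) -> None:
        for rec in records:
            if rec.outcome == "win":
                self.q = update_win(
                    self.q, task.OPTIONS.index(rec.choice), rec.pellets, self.params
                )
            elif rec.outcome == "loss":
                self.q = update_loss(
                    self.q, task.OPTIONS.index(rec.choice), rec.penalty_s, self.params
                )

    def __call__(self, history: Sequence) -> int:
        self._learn(history[self._seen :])
        self._seen = len(history)
        probs = softmax_probs(self.q, self.params.beta)
        self.prob_trace.append(probs)
        return int(self.rng.choice(4, p=probs))

    def end_session(self, records: Sequence) -> None:
        """Learn from any records not yet seen and reset the session cursor."""
        self._learn(records[self._seen :])
        self._seen = 0


@dataclass
class SimulationResult:
    """Forward-simulation output of one agent.

    ``probs`` holds the softmax probability 4-vector *before* each
    choice; the remaining arrays hold the sampled trajectory.
    """

    model_id: str
    probs: np.ndarray  # (n_trials, 4)
    choices: np.ndarray  # option indices
    outcomes: np.ndarray  # "win"/"loss"
    pellets: np.ndarray
    penalties: np.ndarray
    sessions: np.ndarray  # 1-based session index per trial

    def to_frame(self, subject_id: str = "S0") -> pd.DataFrame:
        n = len(self.choices)
        trial_index = np.concatenate(
            [np.arange(1, (self.sessions == s).sum() + 1) for s in np.unique(self.sessions)]
        )
        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "session": self.sessions,
                "trial_index": trial_index,
                "choice": [task.OPTIONS[c] for c in self.choices],
                "outcome": self.outcomes,
                "pellets": self.pellets,
                "penalty_s": self.penalties,
            }
        )


def simulate_agent(
    params: RLParams,
    schedule_set: Optional[Sequence[task.OptionSchedule]] = None,
    n_sessions: int = 40,
    trials_mode: str = "time_budget",
    rng: Optional[np.random.Generator] = None,
    trials_per_session: int = 120,
    session_config: Optional[task.SessionConfig] = None,
) -> SimulationResult:
    """Forward-simulate one agent for ``n_sessions`` sessions.

    ``trials_mode="time_budget"`` runs the 30-minute session engine so
    trial counts emerge from the agent's own choices (risky choices burn
    session time in penalties); ``"fixed_n"`` plays exactly
    ``trials_per_session`` trials per session.  Outcomes are sampled from
    the schedules in both modes; Q carries across sessions.
    """
    if trials_mode not in ("time_budget", "fixed_n"):
        raise ValueError(f"unknown trials_mode {trials_mode!r}")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if schedule_set is None:
        schedule_set = task.default_schedule()
    if rng is None:
        rng = np.random.default_rng()
    if session_config is None:
        session_config = task.SessionConfig()

    agent = QAgentPolicy(params, rng)
    choices: List[int] = []
    outcomes: List[str] = []
    pellets: List[int] = []
    penalties: List[float] = []
    sessions: List[int] = []
    if trials_mode == "time_budget":
        for s in range(1, n_sessions + 1):
            records = task.run_session(agent, schedule_set, session_config, rng, session=s)
            agent.end_session(records)
            for rec in records:
                if rec.outcome in ("win", "loss"):
                    choices.append(task.OPTIONS.index(rec.choice))
                    outcomes.append(rec.outcome)
                    pellets.append(rec.pellets)
                    penalties.append(rec.penalty_s)
                    sessions.append(s)
    else:
        for s in range(1, n_sessions + 1):
            for _ in range(trials_per_session):
                c = agent([])
                outcome, pel, pen = task.play_trial(schedule_set[c], rng)
                if outcome == "win":
                    agent.q = update_win(agent.q, c, pel, params)
                else:
                    agent.q = update_loss(agent.q, c, pen, params)
                choices.append(c)
                outcomes.append(outcome)
                pellets.append(pel)
                penalties.append(pen)
                sessions.append(s)
    return SimulationResult(
        model_id=params.model_id,
        probs=np.array(agent.prob_trace),
        choices=np.array(choices, dtype=np.int64),
        outcomes=np.array(outcomes, dtype=object),
        pellets=np.array(pellets, dtype=np.int64),
        penalties=np.array(penalties, dtype=float),
        sessions=np.array(sessions, dtype=np.int64),
    )
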