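"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rgtlearn.models import MODEL_PARAMS, RLParams
from rgtlearn.task import OPTIONS, default_schedule


def random_params(model_id: str, rng: np.random.Generator) -> RLParams:
    """Random constrained parameters in plausible ranges."""
    draw = {
        "beta": rng.uniform(0.2, 3.0),
        "eta_plus": rng.uniform(0.05, 0.95),
        "eta_minus": rng.uniform(0.05, 0.95),
        "m": rng.uniform(0.01, 0.5),
        "b": rng.uniform(-2.0, 2.0),
        "r": rng.uniform(0.2, 1.2),
        "m_rew": rng.uniform(0.5, 2.0),
    }
    return RLParams(model_id=model_id, **{n: draw[n] for n in MODEL_PARAMS[model_id]})


def random_trials(n: int, rng: np.random.Generator, n_sessions: int = 2) -> pd.DataFrame:
    """Random valid win/loss trial sequence on the canonical schedules."""
    sched = default_schedule()
    rows = []
    per = n // n_sessions
    for i in range(n):
        c = int(rng.integers(0, 4))
        win = rng.random() < sched[c].p_win
        rows.append(
            {
                "session": min(i // per, n_sessions - 1) + 1,
                "trial_index": i % per + 1 if i // per < n_sessions else per + i,
                "choice": OPTIONS[c],
                "outcome": "win" if win else "loss",
                "pellets": sched[c].reward_pellets if win else 0,
                "penalty_s": 0.0 if win else sched[c].penalty_s,
            }
        )
    return pd.DataFrame(rows)


def replay_loglik_oracle(params: RLParams, trials: pd.DataFrame) -> np.ndarray:
    """From-scratch pointwise log-likelihood oracle.

    For every trial t the Q-state is rebuilt by replaying all updates
    from trial 1 starting at Q = 0 (no state reuse), then the softmax
    probability of the observed choice is evaluated fresh.
    """
    choices = [OPTIONS.index(c) for c in trials["choice"]]
    outcomes = list(trials["outcome"])
    pellets = list(trials["pellets"])
    penalties = list(trials["penalty_s"])

    def loss_target(t):
        if params.model_id == "basic":
            return 0.0
        if params.model_id in ("scaled", "reward_scaled"):
            return -params.m * t
        if params.model_id == "scaled_offset":
            return params.b - params.m * t
        return params.b - t**params.r

    def win_target(r):
        return params.m_rew * r if params.model_id == "reward_scaled" else r

    n = len(choices)
    out = np.empty(n)
    for t in range(n):
        q = np.zeros(4)
        for s in range(t):  # full replay, no incremental state
            c = choices[s]
            if outcomes[s] == "win":
                q[c] = q[c] + params.eta_plus * (win_target(pellets[s]) - q[c])
            else:
                q[c] = q[c] + params.eta_minus * (loss_target(penalties[s]) - q[c])
        v = params.beta * q
        out[t] = v[choices[t]] - np.log(np.exp(v - v.max()).sum()) - v.max()
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
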