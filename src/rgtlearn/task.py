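"""Rat gambling task (rGT) reinforcement schedules and session engine.

The rGT offers four response options that trade per-trial reward size
against the probability and duration of time-out penalties.  Options P1
and P2 pair small rewards with short, infrequent time-outs; P3 and P4
pair larger rewards with long, frequent time-outs, so the long-run
pellet-maximizing strategy is to stick to P1/P2 (P2 in particular).
This module encodes those schedules and a time-budget session engine
that turns an arbitrary choice policy into a trial log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

__all__ = [
    "OPTIONS",
    "OptionSchedule",
    "SessionConfig",
    "TrialRecord",
    "CUE_VARIANTS",
    "default_schedule",
    "expected_pellets_per_trial",
    "play_trial",
    "cue_is_played",
    "run_session",
]

#: Canonical option labels, indexed 0..3 throughout the package.
OPTIONS = ("P1", "P2", "P3", "P4")

#: Recognized cue-delivery variants of the task.
CUE_VARIANTS = ("uncued", "standard", "reverse", "outcome", "random50", "loss")


@dataclass(frozen=True)
class OptionSchedule:
    """Reinforcement schedule for a single rGT option.

    Attributes
    ----------
    option_id : str
        One of ``P1``..``P4``.
    reward_pellets : int
        Pellets delivered on a win (1-4).
    p_win : float
        Probability that a choice of this option is rewarded.
    penalty_s : float
        Time-out duration in seconds applied on a loss (5-40 s).
    p_penalty : float
        Probability of a loss; must equal ``1 - p_win``.
    """

    option_id: str
    reward_pellets: int
    p_win: float
    penalty_s: float
    p_penalty: float

    def __post_init__(self) -> None:
        if self.option_id not in OPTIONS:
            raise ValueError(f"unknown option_id {self.option_id!r}")
        if not np.isclose(self.p_win + self.p_penalty, 1.0):
            raise ValueError(
                f"{self.option_id}: p_win + p_penalty must be 1, got "
                f"{self.p_win} + {self.p_penalty}"
            )
        if not 0.0 <= self.p_win <= 1.0:
            raise ValueError("p_win must be a probability")
        if self.reward_pellets not in (1, 2, 3, 4):
            raise ValueError("reward_pellets must be in 1..4")
        if not 5.0 <= self.penalty_s <= 40.0:
            raise ValueError("penalty_s must be within [5, 40] seconds")


@dataclass
class SessionConfig:
    """Timing and event-rate configuration for one simulated session.

    Durations are in seconds.  ``premature_prob`` and ``omission_prob``
    default to zero because model-facing simulations use valid choices
    only; set them positive to emulate impulsive/omitted trials.
    """

    session_length_s: float = 1800.0
    iti_s: float = 5.0
    initiation_latency_s: float = 4.0  # magazine re-entry before the ITI starts
    choice_latency_s: float = 1.0
    collect_latency_s: float = 1.0
    response_window_s: float = 10.0
    premature_prob: float = 0.0
    omission_prob: float = 0.0
    premature_timeout_s: float = 5.0
    cue_variant: str = "uncued"

    def __post_init__(self) -> None:
        for name in (
            "session_length_s",
            "iti_s",
            "initiation_latency_s",
            "choice_latency_s",
            "collect_latency_s",
            "response_window_s",
            "premature_timeout_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.session_length_s <= 0:
            raise ValueError("session_length_s must be positive")
        for name in ("premature_prob", "omission_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.cue_variant not in CUE_VARIANTS:
            raise ValueError(
                f"cue_variant must be one of {CUE_VARIANTS}, got {self.cue_variant!r}"
            )


@dataclass
class TrialRecord:
    """One trial of the rGT: the choice made and its consequence."""

    subject_id: str
    session: int
    trial_index: int
    choice: Optional[str]  # None on premature/omitted trials
    outcome: str  # win | loss | premature | omission
    pellets: int
    penalty_s: float
    cue_played: bool
    clock_s: float  # elapsed session time at trial start
    latency_choice_s: Optional[float] = None
    latency_collect_s: Optional[float] = None


def default_schedule() -> List[OptionSchedule]:
    """The canonical rGT reinforcement schedule.

    P1: 1 pellet, p(win)=0.9, 5 s time-out at p=0.1
    P2: 2 pellets, p(win)=0.8, 10 s time-out at p=0.2
    P3: 3 pellets, p(win)=0.5, 30 s time-out at p=0.5
    P4: 4 pellets, p(win)=0.4, 40 s time-out at p=0.6
    """
    return [
        OptionSchedule("P1", 1, 0.9, 5.0, 0.1),
        OptionSchedule("P2", 2, 0.8, 10.0, 0.2),
        OptionSchedule("P3", 3, 0.5, 30.0, 0.5),
        OptionSchedule("P4", 4, 0.4, 40.0, 0.6),
    ]


def expected_pellets_per_trial(schedule: OptionSchedule) -> float:
    """Expected pellets earned per completed trial of one option."""
    return schedule.p_win * schedule.reward_pellets


def play_trial(
    schedule: OptionSchedule, rng: np.random.Generator
) -> tuple[str, int, float]:
    """Resolve one choice of ``schedule`` into (outcome, pellets, penalty_s)."""
    if rng.random() < schedule.p_win:
        return "win", schedule.reward_pellets, 0.0
    return "loss", 0, schedule.penalty_s


def cue_is_played(cue_variant: str, outcome: str, rng: np.random.Generator) -> bool:
    """Whether the audiovisual cue accompanies this trial's outcome.

    standard / reverse: cue on wins only (they differ in how cue salience
    maps to reward size, which is metadata, not schedule structure);
    outcome: cue on every win and loss; random50: Bernoulli(0.5)
    regardless of outcome; loss: losses only; uncued: never.
    """
    if cue_variant == "uncued":
        return False
    if cue_variant in ("standard", "reverse"):
        return outcome == "win"
    if cue_variant == "outcome":
        return outcome in ("win", "loss")
    if cue_variant == "random50":
        return outcome in ("win", "loss") and bool(rng.random() < 0.5)
    if cue_variant == "loss":
        return outcome == "loss"
    raise ValueError(f"unknown cue_variant {cue_variant!r}")


def run_session(
    policy: Callable[[Sequence[TrialRecord]], int | str],
    schedule_set: Sequence[OptionSchedule],
    config: SessionConfig,
    rng: np.random.Generator,
    subject_id: str = "S0",
    session: int = 1,
) -> List[TrialRecord]:
    """Simulate one free-operant session under a choice policy.

    ``policy`` receives the history of trial records so far (this
    session) and returns the chosen option as an index 0-3 or a label
    ``P1``..``P4``.  Trials accrue until the session clock expires; a
    trial that starts before expiry is completed even if it finishes
    after (free-operant semantics).  Premature responses consume the ITI
    plus a 5 s time-out; omissions consume the ITI plus the full
    response window.
    """
    if not callable(policy):
        raise TypeError("policy must be callable")
    if config.session_length_s <= 0:
        raise ValueError("session_length_s must be positive")
    label_to_idx = {s.option_id: i for i, s in enumerate(schedule_set)}

    records: List[TrialRecord] = []
    clock = 0.0
    trial_index = 1
    while clock < config.session_length_s:
        start = clock
        clock += config.initiation_latency_s + config.iti_s
        # Premature response during the ITI: 5 s time-out, no choice.
        if config.premature_prob > 0 and rng.random() < config.premature_prob:
            clock += config.premature_timeout_s
            records.append(
                TrialRecord(
                    subject_id, session, trial_index, None, "premature",
                    0, 0.0, False, start,
                )
            )
            trial_index += 1
            continue
        # Omission: no response within the window.
        if config.omission_prob > 0 and rng.random() < config.omission_prob:
            clock += config.response_window_s
            records.append(
                TrialRecord(
                    subject_id, session, trial_index, None, "omission",
                    0, 0.0, False, start,
                )
            )
            trial_index += 1
            continue
        chosen = policy(records)
        idx = label_to_idx[chosen] if isinstance(chosen, str) else int(chosen)
        sched = schedule_set[idx]
        outcome, pellets, penalty = play_trial(sched, rng)
        clock += config.choice_latency_s
        if outcome == "win":
            clock += config.collect_latency_s
        else:
            clock += penalty
        records.append(
            TrialRecord(
                subject_id,
                session,
                trial_index,
                sched.option_id,
                outcome,
                pellets,
                penalty,
                cue_is_played(config.cue_variant, outcome, rng),
                start,
                latency_choice_s=config.choice_latency_s,
                latency_collect_s=config.collect_latency_s if outcome == "win" else None,
            )
        )
        trial_index += 1
    return records
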