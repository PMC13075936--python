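"""Canonical trial-log CSV schema, validation, and run configuration.

The interchange format is a long-format RFC-4180 CSV with one row per
initiated trial.  Premature and omitted trials are retained on read but
flagged invalid for modeling (the likelihoods use valid win/loss choices
only).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .task import CUE_VARIANTS, OPTIONS

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "SchemaError",
    "validate_trial_log",
    "read_trial_log",
    "write_trial_log",
    "exclude_incomplete_subjects",
    "RunConfig",
    "load_config",
    "config_hash",
]

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "task_variant",
    "session",
    "trial_index",
    "choice",
    "outcome",
    "pellets",
    "penalty_s",
    "cue_played",
    "premature",
    "omission",
    "latency_choice_s",
    "latency_collect_s",
]

_OUTCOMES = {"win", "loss", "premature", "omission"}


class SchemaError(ValueError):
    """Trial-log schema violation; message lists offending rows."""


def validate_trial_log(df: pd.DataFrame) -> List[str]:
    """Return a list of human-readable violations (empty when valid).

    Row numbers refer to 0-based positions in the frame.
    """
    errors: List[str] = []
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    bad_outcome = ~df["outcome"].isin(_OUTCOMES)
    for i in df.index[bad_outcome][:10]:
        errors.append(f"row {i}: unknown outcome {df.at[i, 'outcome']!r}")
    dup = df.duplicated(subset=["subject_id", "session", "trial_index"])
    for i in df.index[dup][:10]:
        errors.append(
            f"row {i}: duplicate (subject_id, session, trial_index) key "
            f"{tuple(df.loc[i, ['subject_id', 'session', 'trial_index']])}"
        )
    choice = df["choice"].fillna("").astype(str)
    for i in df.index:
        out = df.at[i, "outcome"]
        pel = df.at[i, "pellets"]
        pen = df.at[i, "penalty_s"]
        ch = choice.at[i]
        if df.at[i, "session"] < 1 or df.at[i, "trial_index"] < 1:
            errors.append(f"row {i}: session and trial_index must be >= 1")
        if out == "win":
            if ch not in OPTIONS:
                errors.append(f"row {i}: win without a valid choice")
            if pen != 0:
                errors.append(f"row {i}: outcome=win but penalty_s={pen}")
            if pel <= 0:
                errors.append(f"row {i}: outcome=win but pellets={pel}")
        elif out == "loss":
            if ch not in OPTIONS:
                errors.append(f"row {i}: loss without a valid choice")
            if pel != 0:
                errors.append(f"row {i}: outcome=loss but pellets={pel}")
            if pen <= 0:
                errors.append(f"row {i}: outcome=loss but penalty_s={pen}")
        elif out in ("premature", "omission"):
            if ch != "":
                errors.append(f"row {i}: outcome={out} must not carry a choice")
            if pel != 0 or pen != 0:
                errors.append(f"row {i}: outcome={out} must have zero pellets/penalty")
        if len(errors) > 50:
            errors.append("... further violations suppressed")
            break
    return errors


def write_trial_log(df: pd.DataFrame, path) -> None:
    """Write a trial-log CSV (RFC 4180, header row, no index)."""
    out = df.copy()
    for c in TRIAL_LOG_COLUMNS:
        if c not in out.columns:
            out[c] = ""
    out[TRIAL_LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path, validate: bool = True) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Adds a ``valid_for_modeling`` flag (win/loss rows only).  Raises
    :class:`SchemaError` naming offending rows on violations.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "task_variant": str, "choice": str, "outcome": str},
        keep_default_na=False,
        na_values=[],
    )
    for c in ("session", "trial_index", "pellets"):
        df[c] = pd.to_numeric(df[c]).astype(int)
    for c in ("penalty_s", "latency_choice_s", "latency_collect_s"):
        df[c] = pd.to_numeric(df[c].replace("", np.nan), errors="coerce")
    df["penalty_s"] = df["penalty_s"].fillna(0.0)
    if validate:
        errors = validate_trial_log(df)
        if errors:
            raise SchemaError("invalid trial log:\n" + "\n".join(errors))
    df["valid_for_modeling"] = df["outcome"].isin(["win", "loss"])
    return df


def exclude_incomplete_subjects(
    records: pd.DataFrame, required_sessions: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects lacking any of sessions 1..required_sessions.

    Returns (retained records, exclusion report with subject ids and
    reasons).
    """
    report = []
    keep_ids = []
    for sid, sub in records.groupby("subject_id"):
        have = set(sub["session"].unique())
        missing = [s for s in range(1, required_sessions + 1) if s not in have]
        if missing:
            report.append(
                {
                    "subject_id": sid,
                    "reason": "missing session" + ("s" if len(missing) > 1 else "")
                    + " " + ", ".join(map(str, missing)),
                }
            )
        else:
            keep_ids.append(sid)
    retained = records[records["subject_id"].isin(keep_ids)].copy()
    return retained, pd.DataFrame(report, columns=["subject_id", "reason"])


class ScheduleOverride(BaseModel):
    option_id: str
    reward_pellets: int
    p_win: float
    penalty_s: float

    @field_validator("option_id")
    @classmethod
    def _opt(cls, v):
        if v not in OPTIONS:
            raise ValueError(f"option_id must be one of {OPTIONS}")
        return v


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML/JSON serializable)."""

    schema_version: int = 1
    models: List[str] = Field(default_factory=lambda: ["basic", "nonlinear"])
    cue_variant: str = "uncued"
    n_subjects: int = 12
    n_sessions: int = 5
    fit_window: tuple = (1, 5)
    baseline_k: int = 4
    seed: int = 0
    n_chains: int = 2
    n_warmup: int = 500
    n_samples: int = 500
    schedule_overrides: List[ScheduleOverride] = Field(default_factory=list)
    output_dir: str = "results"

    @field_validator("cue_variant")
    @classmethod
    def _variant(cls, v):
        if v not in CUE_VARIANTS:
            raise ValueError(f"cue_variant must be one of {CUE_VARIANTS}")
        return v

    @field_validator("models")
    @classmethod
    def _models(cls, v):
        from .models import MODEL_IDS

        bad = [m for m in v if m not in MODEL_IDS]
        if bad:
            raise ValueError(f"unknown models {bad}; choose from {MODEL_IDS}")
        return v


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a configuration, for logging provenance."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
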