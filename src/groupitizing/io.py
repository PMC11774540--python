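"""Trial-table serialization and validation.

The on-disk format is plain comma-separated text (UTF-8, Unix newlines,
decimal point) with a fixed header::

    participant,session,task,arrangement,numerosity,configuration,
    response,rt_ms,concurrent_correct

``task`` and ``arrangement`` come from closed vocabularies; numerosity is
5-16; responses are positive integers; the single task with ignored
distractors exists only for grouped arrays; ungrouped trials carry an
empty configuration. ``read_trials`` accepts a ``column_map`` adapter so
externally deposited tables with different column names can be loaded
without editing the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .observer import ARRANGEMENTS, DUAL_TASKS, TASKS

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "validate_trials",
           "TrialValidationError"]

TRIAL_COLUMNS = ["participant", "session", "task", "arrangement", "numerosity",
                 "configuration", "response", "rt_ms", "concurrent_correct"]

NUMEROSITY_RANGE = (5, 16)
_CONCURRENT_VALUES = {"true", "false", "na"}


class TrialValidationError(ValueError):
    """Trial table violates the schema; carries per-row error messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "; ".join(errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        super().__init__(f"{len(errors)} invalid row(s): {preview}{more}")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; returns the (typed) table or raises
    :class:`TrialValidationError` naming every offending row."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError([f"missing column(s): {', '.join(missing)}"])
    df = trials[TRIAL_COLUMNS].copy()
    df["configuration"] = df["configuration"].fillna("").astype(str)
    df.loc[df["configuration"] == "nan", "configuration"] = ""
    df["concurrent_correct"] = df["concurrent_correct"].astype(str).str.lower()

    errors = []

    def flag(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask]:
            errors.append(f"row {idx}: {message}")

    flag(~df["task"].isin(TASKS), "unknown task label")
    flag(~df["arrangement"].isin(ARRANGEMENTS), "unknown arrangement label")
    num = pd.to_numeric(df["numerosity"], errors="coerce")
    flag(num.isna() | (num != num.round()), "non-integer numerosity")
    lo, hi = NUMEROSITY_RANGE
    flag(num.notna() & ((num < lo) | (num > hi)),
         f"numerosity outside [{lo}, {hi}]")
    resp = pd.to_numeric(df["response"], errors="coerce")
    flag(resp.isna() | (resp != resp.round()) | (resp < 1),
         "response must be a positive integer")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    flag(rt.isna() | (rt <= 0), "non-positive response time")
    flag((df["task"] == "single_distractor") & (df["arrangement"] != "grouped"),
         "single_distractor exists only with grouped arrays")
    flag((df["arrangement"] == "ungrouped") & (df["configuration"] != ""),
         "ungrouped trials carry an empty configuration")
    flag(~df["concurrent_correct"].isin(_CONCURRENT_VALUES),
         "concurrent_correct must be true/false/na")
    flag(df["task"].isin(DUAL_TASKS) & (df["concurrent_correct"] == "na"),
         "dual-task trials need a concurrent_correct value")

    if errors:
        raise TrialValidationError(errors)
    df["numerosity"] = num.astype(int)
    df["response"] = resp.astype(int)
    df["rt_ms"] = rt.astype(float)
    return df


def read_trials(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    ``column_map`` renames source columns to the schema (``{"subj":
    "participant", ...}``) before validation, for externally deposited
    tables whose layout differs.
    """
    df = pd.read_csv(Path(path), dtype={"configuration": str}, keep_default_na=False,
                     na_values=[""])
    if column_map:
        df = df.rename(columns=column_map)
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical header."""
    out = trials[TRIAL_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, lineterminator="\n")
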