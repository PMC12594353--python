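"""CSV formats and provenance records.

Trial tables are flat CSVs with columns ``subjID, condition, block, trial,
choice, outcome`` (and optional ``rt_ms``); trials are 1-based in files,
choices are 1/2 with 0 for a missing response, outcomes +1/-1 with 0 for
missing.  Validation errors name the offending row and column.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_choice_csv",
    "write_choice_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "write_provenance",
]

_CHOICE_COLUMNS = ("subjID", "condition", "block", "trial", "choice", "outcome")


class FormatError(ValueError):
    """A CSV violates its documented format."""


def read_choice_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_CHOICE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col, allowed in (("choice", {0, 1, 2}), ("outcome", {-1, 0, 1})):
        values = frame[col]
        bad = ~values.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: row {row + 2}, column {col!r}: value {values.iloc[row]!r} "
                f"not in {sorted(allowed)}"
            )
    mism = (frame["choice"] == 0) != (frame["outcome"] == 0)
    if mism.any():
        row = int(np.flatnonzero(mism.to_numpy())[0])
        raise FormatError(
            f"{path}: row {row + 2}: choice and outcome must be missing (0) together"
        )
    return frame


def write_choice_csv(frame: pd.DataFrame, path) -> None:
    cols = [c for c in (*_CHOICE_COLUMNS, "rt_ms") if c in frame.columns]
    frame[cols].to_csv(path, index=False, lineterminator="\n")


def read_schedule_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"block", "condition", "trial", "correct_option",
                "reward_assigned_to_correct", "reversal"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_schedule_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")


def write_provenance(path, config: dict) -> None:
    """Echo the run configuration (with seeds and version) next to outputs."""
    from . import __version__

    record = {
        "version": __version__,
        "written": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        **config,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
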