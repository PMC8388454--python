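"""I/O and labelling for per-animal hourly behavior budgets.

Collar sensors classify each second of an animal's day into one of six
mutually exclusive states (eating, rumination, rest, mid activity, high
activity, heavy breathing) and report minutes per state per clock hour, so
each animal-hour row must satisfy ``0 <= minutes <= 60`` per state and a row
total of at most 60 (the remainder is unclassified time, e.g. milking-parlor
absence).  "Activity" downstream always means the mid + high aggregate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .reference import BEHAVIORS

logger = logging.getLogger(__name__)

__all__ = [
    "parse_behavior_log",
    "write_behavior_log",
    "aggregate_activity",
    "join_with_stress",
    "BEHAVIOR_COLUMNS",
]

BEHAVIOR_COLUMNS = ["animal_id", "timestamp", *BEHAVIORS]

_SUM_TOL = 1e-9  # float slack on the 60-minute hour budget


def parse_behavior_log(path) -> tuple[pd.DataFrame, int]:
    """Read a behavior CSV; returns ``(records, n_rejected)``.

    Rows where any behavior lies outside [0, 60] or the six-behavior total
    exceeds 60 minutes are rejected and counted.  Malformed files (missing
    header columns, unreadable) raise ``ValueError``.
    """
    try:
        df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse behavior log {path}: {exc}") from exc
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior log {path} is missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    vals = df[list(BEHAVIORS)].apply(pd.to_numeric, errors="coerce")
    in_range = ((vals >= 0) & (vals <= 60)).all(axis=1) & vals.notna().all(axis=1)
    total_ok = vals.sum(axis=1) <= 60.0 + _SUM_TOL
    valid = ts.notna() & in_range & total_ok
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("parse_behavior_log: rejected %d invalid rows", n_rejected)
    out = pd.concat(
        [df.loc[valid, "animal_id"].astype(str),
         ts[valid].rename("hour_start"),
         vals[valid]],
        axis=1,
    ).reset_index(drop=True)
    return out, n_rejected


def write_behavior_log(records: pd.DataFrame, path) -> None:
    """Write records in the CSV layout `parse_behavior_log` reads back."""
    out = records.rename(columns={"hour_start": "timestamp"})
    out[BEHAVIOR_COLUMNS].to_csv(path, index=False)


def aggregate_activity(records: pd.DataFrame) -> pd.DataFrame:
    """Add the aggregated ``activity`` column (mid + high activity minutes)."""
    out = records.copy()
    out["activity"] = out["mid_activity"] + out["high_activity"]
    return out


def join_with_stress(behavior: pd.DataFrame, heat_load: pd.DataFrame) -> pd.DataFrame:
    """Attach each animal-hour's heat-stress label; no rows invented or lost.

    Joins on ``hour_start``.  Behavior hours absent from the heat-load table
    are retained with stress ``UNDEFINED`` and a logged warning.
    """
    labels = heat_load[["hour_start", "stress"]]
    out = aggregate_activity(behavior).merge(labels, on="hour_start", how="left")
    unmatched = out["stress"].isna()
    if unmatched.any():
        logger.warning("join_with_stress: %d records at hours missing from the "
                       "heat-load table; labelled UNDEFINED", int(unmatched.sum()))
        out.loc[unmatched, "stress"] = "UNDEFINED"
    if len(out) != len(behavior):
        raise AssertionError("join changed the record count")  # duplicate hours upstream
    return out
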