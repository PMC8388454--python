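"""Temperature-humidity index (THI), accumulated heat load, and stress classes.

The THI combines dry-bulb temperature and relative humidity into a single
heat-stress exposure index (NRC form)::

    THI = (1.8*T + 32) - (0.55 - 0.555*RH) * (1.8*T - 26)

with T in °C and RH as a *fraction*.  The public interface accepts RH in
percent (0-100) and converts internally; with the 0.555 coefficient the
formula only produces index values in the usual cattle range (~69-74 for a
Mediterranean summer barn) when RH enters as a fraction, matching the
standard NRC 0.0055·RH_pct term.

Heat exposure of an hour is summarized by THI_load, the sum of the hourly
THI over the 24 hours strictly preceding it.  Hours are classified into
quartiles of THI_load; the lowest quartile (Q1) is labelled no stress (NS)
and the highest (Q4) heat stress (HS).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_thi",
    "parse_sensor_log",
    "aggregate_hourly",
    "compute_heat_load",
    "classify_stress",
    "TEMPERATURE_PLAUSIBLE_RANGE",
]

#: Readings outside this dry-bulb window (°C) are rejected as corrupt.
TEMPERATURE_PLAUSIBLE_RANGE = (-30.0, 60.0)

SENSOR_COLUMNS = ["sensor_id", "timestamp", "temperature_c", "rh_pct"]


def compute_thi(temperature, relative_humidity):
    """THI from dry-bulb temperature (°C) and relative humidity (percent).

    Vectorized; returns a scalar for scalar inputs.  At T = 26/1.8 °C the
    humidity term vanishes and THI = 58 regardless of RH.
    """
    t = np.asarray(temperature, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative_humidity must be within [0, 100] percent")
    rh_frac = rh / 100.0
    thi = (1.8 * t + 32.0) - (0.55 - 0.555 * rh_frac) * (1.8 * t - 26.0)
    if np.isscalar(temperature) and np.isscalar(relative_humidity):
        return float(thi)
    return thi


def parse_sensor_log(path) -> tuple[pd.DataFrame, int]:
    """Read an environmental sensor CSV, dropping physically implausible rows.

    Expects header columns ``sensor_id,timestamp,temperature_c,rh_pct`` with
    ISO 8601 timestamps.  Returns ``(samples, n_skipped)`` where rows with RH
    outside [0, 100], temperature outside the plausibility window, or
    unparseable fields are skipped and counted.  A missing header or an
    unreadable file raises ``ValueError``.
    """
    try:
        df = pd.read_csv(path, dtype={"sensor_id": str}, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface parse failure context
        raise ValueError(f"cannot parse sensor log {path}: {exc}") from exc
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor log {path} is missing columns {missing} "
                         f"(header line 1)")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    t = pd.to_numeric(df["temperature_c"], errors="coerce")
    rh = pd.to_numeric(df["rh_pct"], errors="coerce")
    lo, hi = TEMPERATURE_PLAUSIBLE_RANGE
    valid = (
        ts.notna() & t.notna() & rh.notna()
        & rh.between(0.0, 100.0)
        & t.between(lo, hi)
    )
    n_skipped = int((~valid).sum())
    if n_skipped:
        bad = df.index[~valid][:5].tolist()
        logger.warning("parse_sensor_log: skipped %d invalid rows (first rows: %s)",
                       n_skipped, bad)
    out = pd.DataFrame({
        "sensor_id": df.loc[valid, "sensor_id"].astype(str),
        "timestamp": ts[valid],
        "temperature_c": t[valid],
        "rh_pct": rh[valid],
    }).reset_index(drop=True)
    return out, n_skipped


def aggregate_hourly(samples: pd.DataFrame) -> pd.DataFrame:
    """Pool all sensors into hourly mean temperature, mean RH and THI.

    Hours are half-open clock hours [t, t+1); hours without any sample are
    absent from the output.  THI is computed from the hourly means (not
    averaged over per-sample THI values).
    """
    cols = ["hour_start", "mean_t", "mean_rh", "thi", "n_samples"]
    if len(samples) == 0:
        return pd.DataFrame(columns=cols)
    hour = samples["timestamp"].dt.floor("h")
    grouped = samples.groupby(hour).agg(
        mean_t=("temperature_c", "mean"),
        mean_rh=("rh_pct", "mean"),
        n_samples=("temperature_c", "size"),
    )
    grouped.index.name = "hour_start"
    out = grouped.reset_index().sort_values("hour_start").reset_index(drop=True)
    out["thi"] = compute_thi(out["mean_t"].to_numpy(), out["mean_rh"].to_numpy())
    return out[cols]


def compute_heat_load(hourly: pd.DataFrame, window_hours: int = 24,
                      include_current: bool = False) -> pd.DataFrame:
    """Accumulated THI over the 24 hours preceding each hour.

    For hour t the default (causal) window is [t-24, t-1]; set
    ``include_current=True`` for [t-23, t].  The output covers every clock
    hour between the first and last observed hour; ``thi_load`` is NaN with
    quartile/stress ``UNDEFINED`` whenever any hourly THI in the window is
    missing.
    """
    cols = ["hour_start", "thi_load", "quartile", "stress"]
    if len(hourly) == 0:
        return pd.DataFrame(columns=cols)
    idx = pd.date_range(hourly["hour_start"].min(), hourly["hour_start"].max(),
                        freq="h")
    thi = hourly.set_index("hour_start")["thi"].reindex(idx)
    shifted = thi if include_current else thi.shift(1)
    load = shifted.rolling(window_hours, min_periods=window_hours).sum()
    out = pd.DataFrame({
        "hour_start": idx,
        "thi_load": load.to_numpy(),
        "quartile": "UNDEFINED",
        "stress": "UNDEFINED",
    })
    return out


_QUARTILE_STRESS = {"Q1": "NS", "Q2": "INTERMEDIATE", "Q3": "INTERMEDIATE", "Q4": "HS"}


def classify_stress(heat_load: pd.DataFrame,
                    boundaries: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Assign THI_load quartiles and NS/HS stress labels.

    When ``boundaries`` (b1, b2, b3) are not supplied they are estimated as
    the linear-interpolation sample quartiles of the defined loads.  Values
    exactly equal to a boundary fall in the lower group, matching the strict
    inequalities in the Q1/Q4 definitions.  Hours with undefined load stay
    ``UNDEFINED``.
    """
    out = heat_load.copy()
    load = out["thi_load"].to_numpy(dtype=float)
    defined = np.isfinite(load)
    if boundaries is None:
        if defined.sum() < 4:
            raise ValueError("need at least 4 defined thi_load values to "
                             "estimate quartile boundaries")
        b1, b2, b3 = np.quantile(load[defined], [0.25, 0.5, 0.75], method="linear")
    else:
        b1, b2, b3 = (float(b) for b in boundaries)
        if not (b1 <= b2 <= b3):
            raise ValueError("boundaries must be nondecreasing")
    x = load[defined]
    quartile = np.where(x <= b1, "Q1",
                np.where(x <= b2, "Q2",
                np.where(x <= b3, "Q3", "Q4")))
    q = out["quartile"].to_numpy(dtype=object)
    q[defined] = quartile
    out["quartile"] = q
    out["stress"] = [_QUARTILE_STRESS.get(v, "UNDEFINED") for v in out["quartile"]]
    out.attrs["boundaries"] = (float(b1), float(b2), float(b3))
    return out
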