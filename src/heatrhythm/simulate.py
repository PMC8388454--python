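"""Synthetic barn data with the statistical structure the pipeline assumes.

The generator emulates a summer monitoring campaign on a Mediterranean dairy
farm: a network of temperature/humidity sensors logging every 5 minutes, and
collar sensors reporting per-animal hourly minutes for six behaviors.  The
environmental side is a diurnal temperature cycle (peak at 15:00, relative
humidity in anti-phase) with optional heatwave episodes and day-to-day
variation; the behavioral side draws each animal-hour from the reference
circadian models of the stress regime the hour falls in, plus independent
Gaussian noise, truncated at zero and rescaled so the six states never exceed
the 60-minute hour budget.

Two sampling modes are exposed:

* :func:`generate_study` — the full pipeline-shaped dataset (sensor CSV,
  behavior CSV, ground truth), with truncation and budget rescaling applied
  as a real collar would enforce them;
* :func:`sample_from_model` — idealized regression sampling (model value +
  Gaussian noise, no truncation) for parameter-recovery experiments where
  the estimand must equal the generating parameters exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import behavior as behavior_io
from . import thi as thi_mod
from .circadian import CircadianModel
from .reference import BEHAVIORS, MODELLED_BEHAVIORS, REFERENCE_MODELS

__all__ = [
    "HeatwaveEvent",
    "FarmConfig",
    "StudyData",
    "generate_environment",
    "generate_behavior",
    "generate_study",
    "sample_from_model",
]

_BASE_DATE = pd.Timestamp("2020-07-01")


@dataclass(frozen=True)
class HeatwaveEvent:
    """Days [start_day, end_day] (0-based, inclusive) with a temperature offset."""

    start_day: int
    end_day: int
    offset_c: float = 5.0


@dataclass(frozen=True)
class FarmConfig:
    """Study conditions for the synthetic farm.

    Environmental defaults describe a Mediterranean summer (mean ~23 °C,
    extremes 13.8-33.2 °C, mean RH 50%); instrumentation defaults are 15
    sensors at 5-min sampling and 40 collared animals.  Behavior models
    default to the reference circadian equations; noise_sd is the Gaussian
    spread (minutes) of an animal-hour around its model value.  The default
    heatwave covers the second half of a 14-day study so that both stress
    regimes are well represented.
    """

    n_sensors: int = 15
    n_animals: int = 40
    n_days: int = 14
    sample_interval_minutes: int = 5
    temperature_mean: float = 23.0
    temperature_max: float = 33.2
    temperature_min: float = 13.8
    rh_mean: float = 50.0
    rh_amplitude: float = 15.0
    sensor_noise_sd: float = 0.3
    rh_noise_sd: float = 2.0
    day_to_day_sd: float = 1.0
    behavior_noise_sd: float = 5.0
    activity_mid_fraction: float = 0.73
    heatwave_schedule: tuple = (HeatwaveEvent(7, 13, 5.0),)
    models: dict = field(default_factory=lambda: REFERENCE_MODELS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be at least 2 (24-h heat-load warm-up)")
        if not (self.temperature_min < self.temperature_mean < self.temperature_max):
            raise ValueError("need temperature_min < temperature_mean < temperature_max")


@dataclass
class StudyData:
    """All artifacts of one simulated study, plus the generating ground truth."""

    config: FarmConfig
    samples: pd.DataFrame
    truth_hourly: pd.DataFrame
    hourly: pd.DataFrame
    heat_load: pd.DataFrame
    behavior: pd.DataFrame
    boundaries: tuple


def _day_offsets(config: FarmConfig, rng: np.random.Generator) -> np.ndarray:
    offsets = rng.normal(0.0, config.day_to_day_sd, size=config.n_days)
    for ev in config.heatwave_schedule:
        offsets[ev.start_day:ev.end_day + 1] += ev.offset_c
    return offsets


def _diurnal_temperature(hour_of_day, config: FarmConfig):
    """Step-hourly diurnal cycle peaking at 15:00, spanning [min, max] °C."""
    mid = (config.temperature_max + config.temperature_min) / 2.0
    half = (config.temperature_max - config.temperature_min) / 2.0
    return mid + half * np.cos(2 * np.pi * (np.asarray(hour_of_day) - 15.0) / 24.0)


def _diurnal_rh(hour_of_day, config: FarmConfig):
    """RH in anti-phase with temperature (driest mid-afternoon)."""
    return config.rh_mean - config.rh_amplitude * np.cos(
        2 * np.pi * (np.asarray(hour_of_day) - 15.0) / 24.0)


def generate_environment(config: FarmConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the sensor network; returns ``(samples, truth_hourly)``.

    Each sensor reports every ``sample_interval_minutes``; readings are the
    hour's base value (diurnal cycle + that day's offset) plus independent
    Gaussian sensor noise.  ``truth_hourly`` holds the noise-free hourly
    means and the THI computed from them.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    day_off = _day_offsets(config, rng)
    per_hour = 60 // config.sample_interval_minutes
    n_hours = config.n_days * 24

    hours = np.arange(n_hours)
    hod = hours % 24
    true_t = _diurnal_temperature(hod, config) + day_off[hours // 24]
    true_rh = np.clip(_diurnal_rh(hod, config), 5.0, 100.0)
    truth = pd.DataFrame({
        "hour_start": _BASE_DATE + pd.to_timedelta(hours, unit="h"),
        "true_t": true_t,
        "true_rh": true_rh,
        "true_thi": thi_mod.compute_thi(true_t, true_rh),
    })

    n_slots = n_hours * per_hour
    slot_minutes = np.arange(n_slots) * config.sample_interval_minutes
    slot_hour = slot_minutes // 60
    frames = []
    for s in range(config.n_sensors):
        t = true_t[slot_hour] + rng.normal(0.0, config.sensor_noise_sd, n_slots)
        rh = true_rh[slot_hour] + rng.normal(0.0, config.rh_noise_sd, n_slots)
        frames.append(pd.DataFrame({
            "sensor_id": f"S{s + 1:02d}",
            "timestamp": _BASE_DATE + pd.to_timedelta(slot_minutes, unit="m"),
            "temperature_c": t,
            "rh_pct": np.clip(rh, 0.0, 100.0),
        }))
    samples = pd.concat(frames, ignore_index=True)
    samples = samples.sort_values(["timestamp", "sensor_id"]).reset_index(drop=True)
    return samples, truth


def _regime_value(models: dict, behavior: str, stress: str, hour_of_day):
    ns = models[behavior]["NS"].evaluate(hour_of_day)
    hs = models[behavior]["HS"].evaluate(hour_of_day)
    if stress == "NS":
        return ns
    if stress == "HS":
        return hs
    return 0.5 * (ns + hs)  # intermediate / undefined hours: midpoint


def generate_behavior(config: FarmConfig, stress_labels: pd.DataFrame,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate collar records for every animal-hour in ``stress_labels``.

    ``stress_labels`` needs columns ``hour_start`` and ``stress``.  Per
    animal-hour: evaluate the regime's model for the five modelled behaviors,
    add independent Gaussian noise, truncate at 0, split activity into
    mid/high by ``activity_mid_fraction``, then rescale all six states
    proportionally when their total exceeds the 60-minute budget.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    hours = stress_labels["hour_start"].to_numpy()
    stress = stress_labels["stress"].to_numpy()
    hod = pd.DatetimeIndex(hours).hour.to_numpy(dtype=float)
    n_h = hours.size
    n_a = config.n_animals

    base = {}
    for beh in MODELLED_BEHAVIORS:
        vals = np.empty(n_h)
        for regime in ("NS", "HS", "OTHER"):
            mask = (stress == regime) if regime != "OTHER" else ~np.isin(stress, ["NS", "HS"])
            if mask.any():
                vals[mask] = _regime_value(config.models, beh,
                                           regime if regime != "OTHER" else "MID",
                                           hod[mask])
        base[beh] = vals

    noisy = {
        beh: np.clip(base[beh][None, :]
                     + rng.normal(0.0, config.behavior_noise_sd, (n_a, n_h)),
                     0.0, None)
        for beh in MODELLED_BEHAVIORS
    }
    mid = noisy["activity"] * config.activity_mid_fraction
    high = noisy["activity"] - mid
    cols = {
        "eating": noisy["eating"],
        "rumination": noisy["rumination"],
        "rest": noisy["rest"],
        "mid_activity": mid,
        "high_activity": high,
        "heavy_breathing": noisy["heavy_breathing"],
    }
    total = sum(cols.values())
    scale = np.where(total > 60.0, 60.0 / np.where(total > 0, total, 1.0), 1.0)
    for beh in cols:
        cols[beh] = cols[beh] * scale

    animal_ids = np.repeat([f"A{i + 1:03d}" for i in range(n_a)], n_h)
    out = pd.DataFrame({
        "animal_id": animal_ids,
        "hour_start": np.tile(hours, n_a),
    })
    for beh in BEHAVIORS:
        out[beh] = cols[beh].ravel()
    return out.sort_values(["animal_id", "hour_start"]).reset_index(drop=True)


def generate_study(config: FarmConfig, out_dir=None) -> StudyData:
    """Run the full simulation and, optionally, write its file artifacts.

    Environment → hourly THI → 24-h heat load → quartile stress labels →
    behavior conditioned on those labels.  Deterministic for a given seed.
    Writes ``sensors.csv``, ``behavior.csv`` and ``ground_truth.json`` when
    ``out_dir`` is given.
    """
    rng = np.random.default_rng(config.seed)
    samples, truth = generate_environment(config, rng)
    hourly = thi_mod.aggregate_hourly(samples)
    heat_load = thi_mod.classify_stress(thi_mod.compute_heat_load(hourly))
    boundaries = heat_load.attrs["boundaries"]
    beh = generate_behavior(config, heat_load[["hour_start", "stress"]], rng)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        samples.to_csv(out_dir / "sensors.csv", index=False)
        behavior_io.write_behavior_log(beh, out_dir / "behavior.csv")
        truth_bundle = {
            "seed": config.seed,
            "config": _config_dict(config),
            "quartile_boundaries": list(boundaries),
            "models": {
                beh_name: {grp: dataclasses.asdict(m) for grp, m in grps.items()}
                for beh_name, grps in config.models.items()
            },
        }
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truth_bundle, indent=2, default=str))
    return StudyData(config, samples, truth, hourly, heat_load, beh, boundaries)


def _config_dict(config: FarmConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("models")
    d["heatwave_schedule"] = [dataclasses.asdict(ev) if dataclasses.is_dataclass(ev) else ev
                              for ev in config.heatwave_schedule]
    return d


def sample_from_model(model: CircadianModel, n_animals: int = 40, n_days: int = 14,
                      noise_sd: float = 5.0,
                      rng: Optional[np.random.Generator] = None,
                      seed: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    """Idealized animal-hour sample: model value + Gaussian noise, untruncated.

    Returns ``(hours, values)`` with one observation per animal per hour of
    each day (hours of day 0..23).  Because no truncation or budget rescaling
    is applied, the generating parameters are exactly the estimands of a
    least-squares fit on the output.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hours = np.tile(np.arange(24.0), n_days * n_animals)
    values = model.evaluate(hours) + rng.normal(0.0, noise_sd, hours.size)
    return hours, values
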