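"""File formats and run manifests.

Everything on disk is plain text: long-format CSV for schedules and
series, YAML key-value files for configuration, JSON for manifests.
Series round-trip losslessly to 12 significant digits.  Time columns are
canonically in block units; a ``block_minutes`` field in the config makes
minute/hour conversion explicit at the boundary.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import CTParams
from .schedule import BeepSchedule, DelayConfig, ScheduleConfig
from .simulate import TimeSeries

__all__ = [
    "schedule_to_csv",
    "read_schedule",
    "series_to_csv",
    "read_series",
    "load_schedule_config",
    "load_process_config",
    "make_manifest",
    "write_manifest",
]

_FLOAT_FMT = "%.12g"


def schedule_to_csv(
    schedule: BeepSchedule,
    path,
    *,
    block_minutes: float = 90.0,
    person_id: str = "sim",
) -> None:
    """Write beep times as person_id, day, beep_index, time_blocks, time_minutes."""
    beep_index = np.zeros(schedule.n, dtype=int)
    count = 0
    for i in range(schedule.n):
        count = 1 if schedule.is_day_first[i] else count + 1
        beep_index[i] = count
    frame = pd.DataFrame(
        {
            "person_id": person_id,
            "day": schedule.day_index + 1,
            "beep_index": beep_index,
            "time_blocks": schedule.times,
            "time_minutes": schedule.times * block_minutes,
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_schedule(path) -> BeepSchedule:
    frame = pd.read_csv(path)
    day = frame["day"].to_numpy(dtype=int) - 1
    first = np.ones(len(frame), dtype=bool)
    first[1:] = day[1:] != day[:-1]
    return BeepSchedule(
        times=frame["time_blocks"].to_numpy(dtype=float),
        day_index=day,
        is_day_first=first,
    )


def series_to_csv(series: TimeSeries, path) -> None:
    """Write observations as person_id, day, time_blocks, y1..yK."""
    data = {
        "person_id": series.person_id,
        "day": series.day_index + 1,
        "time_blocks": series.times,
    }
    for k in range(series.K):
        data[f"y{k + 1}"] = series.values[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series(path, *, time_unit: str = "blocks", block_minutes: float = 90.0) -> TimeSeries:
    """Read a long CSV; time accepted in blocks, minutes or hours."""
    frame = pd.read_csv(path)
    cols = [c for c in frame.columns if c.startswith("y")]
    if not cols:
        raise ValueError(f"no outcome columns (y1..yK) in {path}")
    time_col = "time_blocks" if "time_blocks" in frame.columns else "time"
    t = frame[time_col].to_numpy(dtype=float)
    if time_unit == "minutes":
        t = t / block_minutes
    elif time_unit == "hours":
        t = t * 60.0 / block_minutes
    elif time_unit != "blocks":
        raise ValueError(f"unknown time unit {time_unit!r}")
    day = (
        frame["day"].to_numpy(dtype=int) - 1
        if "day" in frame.columns
        else np.zeros(len(frame), dtype=int)
    )
    pid = str(frame["person_id"].iloc[0]) if "person_id" in frame.columns else "unknown"
    return TimeSeries(
        person_id=pid,
        times=t,
        values=frame[cols].to_numpy(dtype=float),
        day_index=day,
    )


def load_schedule_config(path) -> tuple[ScheduleConfig, DelayConfig | None]:
    """Read a YAML schedule configuration.

    Top-level keys mirror ScheduleConfig fields; an optional ``delay``
    mapping (DelayConfig fields) switches to the empirical-like generator.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    delay_raw = raw.pop("delay", None)
    sched_keys = ScheduleConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(sched_keys)
    if unknown:
        raise ValueError(f"unknown schedule config keys: {sorted(unknown)}")
    config = ScheduleConfig(**raw)
    delay = DelayConfig(**delay_raw) if delay_raw is not None else None
    return config, delay


def load_process_config(raw: dict) -> CTParams:
    """Build CTParams from a config mapping.

    Either ``phi`` (+ optional ``sigma_y``) for a univariate process, or an
    explicit drift matrix ``B`` with covariance ``Sigma_y``.
    """
    if "phi" in raw:
        return CTParams.from_phi(float(raw["phi"]), float(raw.get("sigma_y", 1.0)))
    if "B" in raw:
        return CTParams(B=raw["B"], Sigma_y=raw.get("Sigma_y", np.eye(len(raw["B"]))))
    raise ValueError("process config needs either 'phi' or 'B'")


def make_manifest(config: dict, seed: int, outputs: list[str], **extra) -> dict:
    from . import __version__

    return {
        "tool": "ctesm",
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "master_seed": seed,
        "config": config,
        "outputs": sorted(outputs),
        **extra,
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
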