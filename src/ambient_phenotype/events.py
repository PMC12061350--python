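"""Sensor event streams, home layouts, covariates and event calendars.

The analysis works on timestamped readings from ambient in-home sensors:
passive-infrared motion detectors (one ON trigger per detection), magnetic
door contacts on external doors (OPEN/CLOSE), and ambient light/temperature
units that emit periodic numeric readings.  All instants are local wall-clock
time at second resolution; the markers are day/time-of-day based so no
timezone arithmetic is performed.

File dialects are deliberately plain:

* event stream — delimited text (comma for ``.csv``, tab for ``.tsv``) with a
  header row ``timestamp,sensor_id,sensor_type,value`` and ISO 8601 local
  timestamps;
* home layout and covariates — YAML or JSON;
* marker tables and AQI calendars — CSV.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SensorType",
    "SensorEvent",
    "HomeLayout",
    "Participant",
    "EventType",
    "EventCalendar",
    "read_events",
    "write_events",
    "read_layout",
    "read_covariates",
    "write_covariates",
    "read_aqi",
    "write_aqi",
    "read_calendar",
    "write_calendar",
    "MARKER_COLUMNS",
    "write_markers",
    "read_markers",
]


class SensorType(str, Enum):
    MOTION = "motion"
    DOOR = "door"
    LIGHT = "light"
    TEMPERATURE = "temperature"


class EventType(str, Enum):
    COVID = "covid"
    SMOKE = "smoke"


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped reading from one sensor.

    ``value`` is ``"ON"`` for motion triggers, ``"OPEN"``/``"CLOSE"`` for door
    contacts, and a decimal string for light (lux-like) and temperature
    (degrees) readings.
    """

    timestamp: dt.datetime
    sensor_id: str
    sensor_type: SensorType
    value: str

    def __post_init__(self) -> None:
        if self.sensor_type is SensorType.DOOR and self.value not in ("OPEN", "CLOSE"):
            raise ValueError(
                f"door event value must be OPEN or CLOSE, got {self.value!r}"
            )


@dataclass(frozen=True)
class HomeLayout:
    """Mapping from sensors to functional areas of a single-resident home.

    ``door_areas`` (areas containing an external door) is derived from the
    areas the external-door sensors are mounted in, plus any explicitly
    declared door areas.
    """

    areas: dict[str, str]                 # sensor_id -> area name
    bedroom_areas: frozenset[str]
    external_doors: frozenset[str]        # sensor_ids of external door contacts
    door_areas: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.bedroom_areas:
            raise ValueError("layout must declare at least one bedroom area")
        if not self.external_doors:
            raise ValueError("layout must declare at least one external door")
        derived = {
            self.areas[s] for s in self.external_doors if s in self.areas
        }
        object.__setattr__(
            self, "door_areas", frozenset(self.door_areas) | derived
        )

    def area_of(self, sensor_id: str) -> str:
        try:
            return self.areas[sensor_id]
        except KeyError:
            raise KeyError(f"sensor {sensor_id!r} is not mapped to an area") from None

    def is_bedroom(self, sensor_id: str) -> bool:
        return self.area_of(sensor_id) in self.bedroom_areas

    def is_door_reading(self, event: SensorEvent) -> bool:
        """True if the reading is from an external door or a door area."""
        if event.sensor_type is SensorType.DOOR:
            return event.sensor_id in self.external_doors
        return self.area_of(event.sensor_id) in self.door_areas


@dataclass(frozen=True)
class Participant:
    participant_id: str
    age: float
    gender: str  # "female" | "male" | "unreported"
    education: float
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.education < 0:
            raise ValueError("education must be non-negative")
        if self.gender not in ("female", "male", "unreported"):
            raise ValueError(f"unknown gender {self.gender!r}")


@dataclass(frozen=True)
class EventCalendar:
    """Which calendar dates constitute the adverse external event.

    For a pandemic lockdown the event is a fixed date range; for wildfire
    smoke it is defined implicitly by a daily air-quality-index series
    (event day: AQI > 100 sustained for >= 2 consecutive days; baseline day:
    AQI <= 50 in the same month).
    """

    event_type: EventType
    lockdown_start: dt.date | None = None
    lockdown_end: dt.date | None = None
    aqi: pd.Series | None = None  # index: dt.date, values: int

    def __post_init__(self) -> None:
        if self.event_type is EventType.COVID:
            if self.lockdown_start is None or self.lockdown_end is None:
                raise ValueError("covid calendar needs a lockdown start and end")
            if self.lockdown_end < self.lockdown_start:
                raise ValueError("lockdown end precedes start")
        else:
            if self.aqi is None:
                raise ValueError("smoke calendar needs a daily AQI series")
            if (self.aqi < 0).any():
                raise ValueError("AQI values must be non-negative")


# ---------------------------------------------------------------------------
# event streams


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_events(path: str | Path) -> list[SensorEvent]:
    """Read a sensor event stream, sorted by timestamp.

    Lines with an unparseable timestamp or unknown sensor type are skipped;
    a single warning reports how many were dropped.  Sorting is stable, so
    equal-timestamp events keep file order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    expected = ["timestamp", "sensor_id", "sensor_type", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    known = df["sensor_type"].isin([t.value for t in SensorType])
    ok = ts.notna() & known
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} malformed event line(s)", stacklevel=2)
    events = [
        SensorEvent(
            t.to_pydatetime(),
            row.sensor_id,
            SensorType(row.sensor_type),
            row.value,
        )
        for t, row in zip(ts[ok], df[ok].itertuples(index=False))
    ]
    events.sort(key=lambda e: e.timestamp)  # timsort: stable for equal stamps
    return events


def write_events(events: Iterable[SensorEvent], path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["timestamp", "sensor_id", "sensor_type", "value"]) + "\n")
        for e in events:
            fh.write(
                sep.join(
                    [e.timestamp.isoformat(sep=" "), e.sensor_id, e.sensor_type.value, e.value]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# layout


def _load_config(path: Path) -> dict:
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def read_layout(path: str | Path) -> HomeLayout:
    """Read a home layout config (YAML or JSON).

    Schema::

        sensors:            # list, so duplicate mappings are detectable
          - {id: m1, area: bedroom}
          - {id: d1, area: entry}
        bedrooms: [bedroom]
        external_doors: [d1]
        door_areas: [entry]   # optional; derived from external doors anyway
    """
    cfg = _load_config(Path(path))
    areas: dict[str, str] = {}
    for entry in cfg.get("sensors", []):
        sid, area = str(entry["id"]), str(entry["area"])
        if sid in areas:
            raise ValueError(f"sensor {sid!r} mapped to two areas")
        areas[sid] = area
    bedrooms = cfg.get("bedrooms")
    if not bedrooms:
        raise ValueError("layout config missing a non-empty 'bedrooms' list")
    doors = cfg.get("external_doors")
    if not doors:
        raise ValueError("layout config missing a non-empty 'external_doors' list")
    return HomeLayout(
        areas=areas,
        bedroom_areas=frozenset(map(str, bedrooms)),
        external_doors=frozenset(map(str, doors)),
        door_areas=frozenset(map(str, cfg.get("door_areas", []))),
    )


def layout_to_config(layout: HomeLayout) -> dict:
    return {
        "sensors": [{"id": s, "area": a} for s, a in sorted(layout.areas.items())],
        "bedrooms": sorted(layout.bedroom_areas),
        "external_doors": sorted(layout.external_doors),
        "door_areas": sorted(layout.door_areas),
    }


def write_layout(layout: HomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_to_config(layout), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# covariates


def read_covariates(path: str | Path) -> list[Participant]:
    cfg = _load_config(Path(path))
    out = []
    for row in cfg["participants"]:
        out.append(
            Participant(
                participant_id=str(row["id"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                education=float(row["education"]),
                conditions=tuple(row.get("conditions", [])),
            )
        )
    return out


def write_covariates(participants: Sequence[Participant], path: str | Path) -> None:
    cfg = {
        "participants": [
            {
                "id": p.participant_id,
                "age": p.age,
                "gender": p.gender,
                "education": p.education,
                "conditions": list(p.conditions),
            }
            for p in participants
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def covariates_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    """Covariates as a DataFrame indexed by participant_id."""
    return pd.DataFrame(
        {
            "age": [p.age for p in participants],
            "gender": [p.gender for p in participants],
            "education": [p.education for p in participants],
        },
        index=pd.Index([p.participant_id for p in participants], name="participant_id"),
    )


# ---------------------------------------------------------------------------
# calendars


def read_aqi(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    dates = pd.to_datetime(df["date"]).dt.date
    s = pd.Series(df["aqi"].astype(int).to_numpy(), index=dates, name="aqi")
    return s.sort_index()


def write_aqi(aqi: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"date": [d.isoformat() for d in aqi.index], "aqi": aqi.to_numpy()}).to_csv(
        path, index=False
    )


def read_calendar(path: str | Path) -> EventCalendar:
    """Read an event calendar config (YAML/JSON).

    Covid: ``{event_type: covid, lockdown_start: ..., lockdown_end: ...}``.
    Smoke: ``{event_type: smoke, aqi_file: path}`` or an inline
    ``aqi: [{date: ..., aqi: ...}, ...]`` list.
    """
    path = Path(path)
    cfg = _load_config(path)
    etype = EventType(cfg["event_type"])
    if etype is EventType.COVID:
        return EventCalendar(
            event_type=etype,
            lockdown_start=_as_date(cfg["lockdown_start"]),
            lockdown_end=_as_date(cfg["lockdown_end"]),
        )
    if "aqi_file" in cfg:
        aqi = read_aqi(path.parent / cfg["aqi_file"])
    else:
        aqi = pd.Series(
            [int(r["aqi"]) for r in cfg["aqi"]],
            index=[_as_date(r["date"]) for r in cfg["aqi"]],
            name="aqi",
        ).sort_index()
    return EventCalendar(event_type=etype, aqi=aqi)


def write_calendar(calendar: EventCalendar, path: str | Path) -> None:
    if calendar.event_type is EventType.COVID:
        cfg = {
            "event_type": "covid",
            "lockdown_start": calendar.lockdown_start.isoformat(),
            "lockdown_end": calendar.lockdown_end.isoformat(),
        }
    else:
        cfg = {
            "event_type": "smoke",
            "aqi": [
                {"date": d.isoformat(), "aqi": int(v)}
                for d, v in calendar.aqi.items()
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _as_date(x) -> dt.date:
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


# ---------------------------------------------------------------------------
# marker tables

MARKER_COLUMNS = [
    "participant_id",
    "date",
    "sleep_duration",
    "sleep_efficiency",
    "restlessness",
    "time_out",
    "activity_level",
    "restlessness_raw",
    "activity_raw",
    "valid",
    "invalid_reason",
]


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    """Write a daily-marker table, one row per participant-day.

    Missing values (e.g. undefined sleep efficiency) are written as empty
    fields; the table round-trips losslessly through :func:`read_markers`.
    """
    df = markers.reindex(columns=MARKER_COLUMNS)
    df = df.assign(
        date=[d.isoformat() if not isinstance(d, str) else d for d in df["date"]]
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty and list(df.columns) == MARKER_COLUMNS:
        df = df.astype({"valid": bool})
    if not df.empty:
        df["date"] = pd.to_datetime(df["date"]).dt.date
        df["participant_id"] = df["participant_id"].astype(str)
        df["valid"] = df["valid"].astype(bool)
        df["invalid_reason"] = df["invalid_reason"].fillna("none")
    return df
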