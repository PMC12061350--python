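"""Daily digital behavior markers extracted from ambient sensor streams.

Five per-day markers summarize a single resident's behavior:

* **sleep duration** — time in bed between the night's first and last detected
  sleep (seconds);
* **sleep efficiency** — ratio of summed sleep time to that span;
* **restlessness** — motion readings generated while asleep (z-scored per
  person);
* **time out** — time spent outside the home (seconds);
* **activity level** — motion readings per hour while home and awake
  (z-scored per person).

Sleep is detected between 21:00 and 07:00: a gap between motion readings is
sleep when it is at least five minutes long and the reading opening the gap
came from a bedroom area.  A run of three or more contiguous non-bedroom
readings flips the state to awake; an awake episode bracketed by sleep within
the same night is a sleep interruption rather than the end of sleep.

Out-of-home episodes start when, while awake, more than twenty minutes pass
without a reading and the most recent readings came from an external door or
a door area; they end at the first reading of the next run of three or more
interior readings.

Normalization uses a per-person standard scaler over all of a person's valid
days (both study periods pooled), because count-based markers depend on the
number and density of sensors installed in each home.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    EventCalendar,
    EventType,
    HomeLayout,
    SensorEvent,
    SensorType,
)

__all__ = [
    "SleepRecord",
    "StudyWindow",
    "SLEEP_WINDOW_START",
    "SLEEP_WINDOW_END",
    "detect_sleep",
    "detect_time_out",
    "compute_daily_markers",
    "extract_markers",
    "normalize_person",
    "filter_days",
    "select_windows",
]

logger = logging.getLogger(__name__)

SLEEP_WINDOW_START = dt.time(21, 0)  # 9 pm
SLEEP_WINDOW_END = dt.time(7, 0)     # 7 am next day
SLEEP_GAP = dt.timedelta(minutes=5)
OUT_GAP = dt.timedelta(minutes=20)
AWAKE_RUN = 3          # >2 contiguous non-bedroom readings flip to awake
INTERIOR_RUN = 3       # >2 interior readings end an out-of-home episode
HALF_DAY_S = 43_200.0  # "out more than half the day" validity threshold

MARKER_NAMES = [
    "sleep_duration",
    "sleep_efficiency",
    "restlessness",
    "time_out",
    "activity_level",
]


@dataclass
class SleepRecord:
    """One night's detected sleep (the night starting 21:00 on ``night_date``)."""

    night_date: dt.date
    segments: list[tuple[dt.datetime, dt.datetime]] = field(default_factory=list)
    interruptions: list[tuple[dt.datetime, dt.datetime]] = field(default_factory=list)
    restless_readings: int = 0

    @property
    def first_sleep(self) -> dt.datetime | None:
        return self.segments[0][0] if self.segments else None

    @property
    def last_sleep(self) -> dt.datetime | None:
        return self.segments[-1][1] if self.segments else None

    @property
    def duration_s(self) -> float:
        if not self.segments:
            return 0.0
        return (self.last_sleep - self.first_sleep).total_seconds()

    @property
    def sleep_time_s(self) -> float:
        return sum((b - a).total_seconds() for a, b in self.segments)

    @property
    def efficiency(self) -> float | None:
        span = self.duration_s
        return None if span == 0 else self.sleep_time_s / span


@dataclass
class StudyWindow:
    """Paired nonevent/event date sets with the interruption point.

    Day indices run over the ordered nonevent dates followed by the ordered
    event dates; the interruption index ``t0`` is the index of the first
    event date.  For contiguous calendar ranges the index equals the
    calendar-day offset, and days later removed by validity filters keep
    their index (time stays calendar time).
    """

    event_type: EventType
    nonevent_dates: list[dt.date]
    event_dates: list[dt.date]

    def __post_init__(self) -> None:
        self.nonevent_dates = sorted(self.nonevent_dates)
        self.event_dates = sorted(self.event_dates)
        if set(self.nonevent_dates) & set(self.event_dates):
            raise ValueError("nonevent and event date sets overlap")

    @property
    def t0(self) -> int:
        return len(self.nonevent_dates)

    def day_index(self) -> dict[dt.date, int]:
        idx = {d: i for i, d in enumerate(self.nonevent_dates)}
        idx.update(
            {d: self.t0 + j for j, d in enumerate(self.event_dates)}
        )
        return idx

    def period_of(self, date: dt.date) -> str | None:
        if date in set(self.event_dates):
            return "event"
        if date in set(self.nonevent_dates):
            return "nonevent"
        return None


# ---------------------------------------------------------------------------
# sleep detection


def _night_window(night_date: dt.date) -> tuple[dt.datetime, dt.datetime]:
    start = dt.datetime.combine(night_date, SLEEP_WINDOW_START)
    end = dt.datetime.combine(night_date + dt.timedelta(days=1), SLEEP_WINDOW_END)
    return start, end


def detect_sleep(
    events: list[SensorEvent],
    layout: HomeLayout,
    night_date: dt.date,
) -> SleepRecord:
    """Run the nighttime sleep state machine for one 21:00–07:00 window.

    ``events`` may be the full stream; only motion readings inside the window
    are used.  Returns an empty record (no sleep detected) if the window has
    no qualifying gap.
    """
    start, end = _night_window(night_date)
    motion = [
        e
        for e in events
        if e.sensor_type is SensorType.MOTION and start <= e.timestamp < end
    ]
    rec = SleepRecord(night_date=night_date)
    if not motion:
        return rec

    bedroom = [layout.is_bedroom(e.sensor_id) for e in motion]
    n = len(motion)
    asleep = False
    seg_start: dt.datetime | None = None
    awake_start: dt.datetime | None = None  # candidate interruption start
    interior = 0  # readings seen strictly inside the current segment

    def close_segment(at: dt.datetime, counted_closer: bool) -> None:
        nonlocal asleep, interior
        rec.segments.append((seg_start, at))
        rec.restless_readings += interior - (1 if counted_closer and interior else 0)
        interior = 0
        asleep = False

    i = 0
    while i < n:
        e, in_bed = motion[i], bedroom[i]
        if asleep:
            # a run of >=3 contiguous non-bedroom readings flips to awake
            if not in_bed and i + AWAKE_RUN <= n and not any(
                bedroom[i : i + AWAKE_RUN]
            ):
                close_segment(e.timestamp, counted_closer=False)
                awake_start = e.timestamp
                i += 1
                continue
            interior += 1
            last_seen = e.timestamp
            i += 1
            continue
        # awake: does the gap opened by this reading qualify as sleep?
        nxt = motion[i + 1].timestamp if i + 1 < n else end
        if in_bed and (nxt - e.timestamp) >= SLEEP_GAP:
            if rec.segments and awake_start is not None:
                rec.interruptions.append((awake_start, e.timestamp))
            awake_start = None
            asleep = True
            seg_start = e.timestamp
            interior = 0
            if i + 1 == n:  # gap runs to the window edge
                close_segment(end, counted_closer=False)
                break
        i += 1
    if asleep:
        # window ended while asleep: the last reading seen is the closer
        close_segment(last_seen, counted_closer=True)
    return rec


# ---------------------------------------------------------------------------
# out-of-home detection


def detect_time_out(
    events: list[SensorEvent],
    layout: HomeLayout,
    day: dt.date,
    asleep_intervals: list[tuple[dt.datetime, dt.datetime]] | None = None,
) -> list[tuple[dt.datetime, dt.datetime, bool]]:
    """Detect out-of-home intervals for one calendar day.

    Returns ``(start, end, open_ended)`` tuples clipped to the day;
    ``open_ended`` marks an episode still in progress at midnight.
    ``asleep_intervals`` (from :func:`detect_sleep` on the bracketing nights)
    suppress detection while the resident is asleep — a long nighttime gap in
    the bedroom is sleep, not absence.
    """
    day_start = dt.datetime.combine(day, dt.time(0, 0))
    day_end = day_start + dt.timedelta(days=1)
    asleep_intervals = asleep_intervals or []

    def is_asleep(t: dt.datetime) -> bool:
        return any(a <= t < b for a, b in asleep_intervals)

    readings = [
        e
        for e in events
        if e.sensor_type in (SensorType.MOTION, SensorType.DOOR)
        and day_start <= e.timestamp < day_end
    ]
    out: list[tuple[dt.datetime, dt.datetime, bool]] = []
    n = len(readings)
    i = 0
    while i < n:
        e = readings[i]
        nxt_t = readings[i + 1].timestamp if i + 1 < n else day_end
        gap_ok = (nxt_t - e.timestamp) > OUT_GAP
        if gap_ok and not is_asleep(e.timestamp) and layout.is_door_reading(e):
            start = e.timestamp
            # episode ends at the first reading of the next run of >=3
            # contiguous interior (motion) readings
            j = i + 1
            end_t: dt.datetime | None = None
            while j + INTERIOR_RUN <= n:
                if all(
                    r.sensor_type is SensorType.MOTION
                    for r in readings[j : j + INTERIOR_RUN]
                ):
                    end_t = readings[j].timestamp
                    break
                j += 1
            if end_t is None:
                out.append((start, day_end, True))
                break
            out.append((start, end_t, False))
            i = j
            continue
        i += 1
    return out


# ---------------------------------------------------------------------------
# per-day markers


def _overlap_s(
    intervals: list[tuple[dt.datetime, dt.datetime]],
    lo: dt.datetime,
    hi: dt.datetime,
) -> float:
    tot = 0.0
    for a, b in intervals:
        s, e = max(a, lo), min(b, hi)
        if e > s:
            tot += (e - s).total_seconds()
    return tot


def compute_daily_markers(
    events: list[SensorEvent],
    layout: HomeLayout,
    participant_id: str,
    date: dt.date,
    *,
    night: SleepRecord | None = None,
    prev_night: SleepRecord | None = None,
) -> dict:
    """Raw (pre-normalization) markers for one participant-day.

    The night beginning 21:00 on ``date`` contributes the day's sleep
    markers; ``prev_night`` (the night of ``date - 1``) is only used to mark
    early-morning hours of ``date`` as asleep for the awake/at-home
    accounting.  Undefined sleep efficiency (no sleep detected) is recorded
    as missing and the day retained.
    """
    if night is None:
        night = detect_sleep(events, layout, date)
    if prev_night is None:
        prev_night = detect_sleep(events, layout, date - dt.timedelta(days=1))

    day_start = dt.datetime.combine(date, dt.time(0, 0))
    day_end = day_start + dt.timedelta(days=1)

    asleep = prev_night.segments + night.segments
    outs = detect_time_out(events, layout, date, asleep_intervals=asleep)
    time_out = sum((b - a).total_seconds() for a, b, _ in outs)

    day_events = [e for e in events if day_start <= e.timestamp < day_end]
    motion = [e for e in day_events if e.sensor_type is SensorType.MOTION]

    def awake_home(t: dt.datetime) -> bool:
        if any(a <= t < b for a, b in asleep):
            return False
        return not any(a <= t < b for a, b, _ in outs)

    sleep_overlap = _overlap_s(asleep, day_start, day_end)
    awake_home_s = 86_400.0 - sleep_overlap - _overlap_s(
        [(a, b) for a, b, _ in outs], day_start, day_end
    )
    n_home_awake = sum(awake_home(e.timestamp) for e in motion)
    activity_raw = (
        n_home_awake / (awake_home_s / 3600.0) if awake_home_s > 60 else np.nan
    )

    valid = True
    reason = "none"
    if not day_events:
        valid, reason = False, "sensor_failure"

    return {
        "participant_id": participant_id,
        "date": date,
        "sleep_duration": night.duration_s,
        "sleep_efficiency": np.nan if night.efficiency is None else night.efficiency,
        "restlessness_raw": float(night.restless_readings),
        "time_out": time_out,
        "activity_raw": activity_raw,
        "valid": valid,
        "invalid_reason": reason,
    }


def extract_markers(
    events: list[SensorEvent],
    layout: HomeLayout,
    participant_id: str,
    dates: list[dt.date] | None = None,
) -> pd.DataFrame:
    """Per-day raw markers for every date covered by the stream (or ``dates``).

    A trailing date whose only events fall before noon is the final night's
    spillover past midnight, not a monitored day, and is dropped.
    """
    if dates is None:
        if not events:
            return pd.DataFrame(
                columns=[
                    "participant_id", "date", "sleep_duration", "sleep_efficiency",
                    "restlessness_raw", "time_out", "activity_raw", "valid",
                    "invalid_reason",
                ]
            )
        d0 = events[0].timestamp.date()
        d1 = events[-1].timestamp.date()
        last_noon = dt.datetime.combine(d1, dt.time(12, 0))
        if d1 > d0 and not any(e.timestamp >= last_noon for e in events):
            d1 -= dt.timedelta(days=1)
        dates = [d0 + dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]
    by_date: dict[dt.date, list[SensorEvent]] = {}
    for e in events:
        by_date.setdefault(e.timestamp.date(), []).append(e)

    def ctx(d: dt.date) -> list[SensorEvent]:
        one = dt.timedelta(days=1)
        return (
            by_date.get(d - one, []) + by_date.get(d, []) + by_date.get(d + one, [])
        )

    nights = {d: detect_sleep(ctx(d), layout, d) for d in dates}
    rows = [
        compute_daily_markers(
            ctx(d), layout, participant_id, d,
            night=nights[d],
            prev_night=nights.get(d - dt.timedelta(days=1))
            or detect_sleep(ctx(d - dt.timedelta(days=1)), layout, d - dt.timedelta(days=1)),
        )
        for d in dates
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normalization and filtering


def normalize_person(markers: pd.DataFrame) -> pd.DataFrame:
    """Z-score count-based markers per person over all their valid days.

    Restlessness and activity level get ``(x - mean) / sd`` with the
    population standard deviation, pooled over both study periods.  Zero
    variance yields all-zero normalized values with a warning.
    """
    out = markers.copy()
    out["restlessness"] = np.nan
    out["activity_level"] = np.nan
    for pid, grp in markers.groupby("participant_id"):
        mask = grp["valid"].to_numpy(dtype=bool)
        if mask.sum() < 2:
            warnings.warn(
                f"participant {pid}: fewer than 2 valid days, markers left unscaled",
                stacklevel=2,
            )
            continue
        for raw, col in [("restlessness_raw", "restlessness"), ("activity_raw", "activity_level")]:
            x = grp.loc[mask, raw].to_numpy(dtype=float)
            finite = np.isfinite(x)
            mu = np.nanmean(x) if finite.any() else np.nan
            sd = np.nanstd(x) if finite.any() else np.nan  # population SD
            vals = grp[raw].to_numpy(dtype=float)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(
                    f"participant {pid}: zero variance in {raw}, normalized to 0",
                    stacklevel=2,
                )
                z = np.where(np.isfinite(vals), 0.0, np.nan)
            else:
                z = (vals - mu) / sd
            out.loc[grp.index, col] = z
    return out


def filter_days(
    markers: pd.DataFrame, window: StudyWindow | None = None
) -> pd.DataFrame:
    """Apply day-validity rules and (optionally) restrict to a study window.

    A day is invalid when the participant was out of the home more than half
    the day (time_out > 43,200 s) or when no sensor reported at all
    (sensor failure).  Flagged days are excluded from all downstream
    statistics; the returned frame contains only valid rows, with flags
    updated in place on the input's copy.
    """
    out = markers.copy()
    over = out["time_out"].to_numpy(dtype=float) > HALF_DAY_S
    newly = over & out["valid"].to_numpy(dtype=bool)
    out.loc[newly, "valid"] = False
    out.loc[newly, "invalid_reason"] = "out_over_half_day"
    n_out = int(newly.sum())
    n_fail = int((out["invalid_reason"] == "sensor_failure").sum())
    if window is not None:
        in_window = out["date"].map(lambda d: window.period_of(d) is not None)
        out = out[in_window]
    logger.info(
        "filter_days: %d day(s) removed (out_over_half_day=%d, sensor_failure=%d)",
        int((~out["valid"]).sum()), n_out, n_fail,
    )
    return out[out["valid"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# window selection


def select_windows(
    event_type: EventType,
    calendar: EventCalendar,
    available_dates: list[dt.date],
) -> StudyWindow:
    """Select paired event / nonevent day sets from an event calendar.

    Covid: event days are the lockdown range intersected with the available
    dates; nonevent days are the season-matched same month/day span one year
    earlier.  Smoke: event days are maximal runs of >= 2 consecutive days
    with AQI > 100; nonevent days are equally many AQI <= 50 days from the
    same calendar month, closest to the run by date.
    """
    avail = set(available_dates)
    if event_type is EventType.COVID:
        n_days = (calendar.lockdown_end - calendar.lockdown_start).days + 1
        event = [
            calendar.lockdown_start + dt.timedelta(days=i) for i in range(n_days)
        ]
        nonevent = [_year_earlier(d) for d in event]
        event = [d for d in event if d in avail]
        nonevent = [d for d in nonevent if d in avail]
        return StudyWindow(EventType.COVID, nonevent, event)

    aqi = calendar.aqi
    dates = list(aqi.index)
    runs: list[list[dt.date]] = []
    cur: list[dt.date] = []
    for d in dates:
        if aqi[d] > 100 and (not cur or (d - cur[-1]).days == 1):
            cur.append(d)
        else:
            if len(cur) >= 2:
                runs.append(cur)
            cur = [d] if aqi[d] > 100 else []
    if len(cur) >= 2:
        runs.append(cur)
    event: list[dt.date] = [d for run in runs for d in run if d in avail]
    if not runs:
        warnings.warn("no AQI run of >=2 consecutive days >100; empty window", stacklevel=2)
    event_set = set(d for run in runs for d in run)
    nonevent: list[dt.date] = []
    taken: set[dt.date] = set()
    for run in runs:
        month_key = (run[0].year, run[0].month)
        candidates = [
            d
            for d in dates
            if (d.year, d.month) == month_key
            and aqi[d] <= 50
            and d not in event_set
            and d not in taken
            and d in avail
        ]
        want = len([d for d in run if d in avail])
        candidates.sort(key=lambda d: (min(abs((d - r).days) for r in run), d))
        chosen = candidates[:want]
        if len(chosen) < want:
            warnings.warn(
                f"only {len(chosen)} baseline day(s) with AQI<=50 available in "
                f"{month_key[0]}-{month_key[1]:02d} for a {want}-day smoke run",
                stacklevel=2,
            )
        taken.update(chosen)
        nonevent.extend(chosen)
    return StudyWindow(EventType.SMOKE, nonevent, event)


def _year_earlier(d: dt.date) -> dt.date:
    try:
        return d.replace(year=d.year - 1)
    except ValueError:  # Feb 29
        return d.replace(year=d.year - 1, day=28)
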