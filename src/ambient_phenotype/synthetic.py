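"""Synthetic single-resident homes and marker time series.

Two generators with different purposes:

* :func:`simulate_home` emits raw sensor event streams (motion, door, and
  uninformative light/temperature background) following a daily routine —
  night sleep with restlessness and occasional interruptions, daytime
  outings bracketed by door events, and indoor activity while home and
  awake — together with a ground-truth daily log for oracle testing.  An
  external event perturbs the routine drivers by an immediate level shift
  plus a per-day linear trend.

* :func:`simulate_marker_series` emits daily marker values directly from the
  segmented linear model the impact analysis fits:
  ``X_t = b0 + b1*t`` before the event and
  ``X_t = b0 + b1*t + b2 + b3*(t - t0)`` during it, plus Gaussian noise.

Event counts (restlessness, indoor activity) are homogeneous Poisson within
their windows; the daily outing count is Poisson truncated at 4; times are
Gaussian clipped to their windows.  These distributional forms are package
choices — the simplest structure that exercises every extraction rule — not
claims about real homes.

The bundled presets encode published interrupted-time-series coefficient
sets for a pandemic-lockdown condition (13 participants, 66 days per side)
and a wildfire-smoke condition (28 participants), so simulated series carry
a known immediate impact and trend change per marker.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import (
    EventCalendar,
    EventType,
    HomeLayout,
    Participant,
    SensorEvent,
    SensorType,
)
from . import markers as _markers

__all__ = [
    "RoutineParams",
    "EventEffect",
    "SimulationSpec",
    "default_layout",
    "simulate_home",
    "simulate_covariates",
    "simulate_marker_series",
    "covid_preset",
    "smoke_preset",
    "spec_to_dict",
    "spec_from_dict",
    "write_spec",
    "read_spec",
]

_MIN = 60.0
_HR = 3600.0


@dataclass
class RoutineParams:
    """Population-level daily-routine parameters for one resident.

    Times of day are minutes after midnight; rates are events per hour;
    durations are minutes.  Bedtime must fall in [19:00, 24:00) and wake in
    [04:00, 11:00); the simulator further clips both into the 21:00–07:00
    sleep-detection window so detected and true sleep coincide.
    """

    bedtime_mean: float = 22 * 60 + 10   # 22:10
    bedtime_sd: float = 20.0
    wake_mean: float = 6 * 60 + 12       # 06:12 -> ~8 h nominal sleep
    wake_sd: float = 15.0
    restlessness_rate: float = 1.0       # bedroom readings per hour asleep
    interruption_prob: float = 0.15      # nights with a bathroom interruption
    interruption_dur_mean: float = 12.0  # minutes
    interruption_dur_sd: float = 4.0
    outings_per_day: float = 1.5         # Poisson mean, truncated at 4
    outing_dur_mean: float = 120.0       # minutes
    outing_dur_sd: float = 30.0
    activity_rate: float = 15.0          # readings per hour home & awake
    area_probs: dict[str, float] = field(
        default_factory=lambda: {
            "kitchen": 0.30, "living": 0.40, "bathroom": 0.20, "office": 0.10,
        }
    )

    def validate(self) -> None:
        if not (19 * 60 <= self.bedtime_mean < 24 * 60):
            raise ValueError("bedtime mean must lie in [19:00, 24:00)")
        if not (4 * 60 <= self.wake_mean < 11 * 60):
            raise ValueError("wake mean must lie in [04:00, 11:00)")
        for name in ("restlessness_rate", "outings_per_day", "activity_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bedtime_sd", "wake_sd", "outing_dur_sd", "interruption_dur_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.interruption_prob <= 1:
            raise ValueError("interruption_prob must be in [0, 1]")
        if abs(sum(self.area_probs.values()) - 1) > 1e-9:
            raise ValueError("area visit probabilities must sum to 1")


@dataclass
class EventEffect:
    """Event-induced change in the routine drivers.

    Each pair is ``(immediate shift, per-day trend during the event)`` in the
    driver's own units: seconds for sleep duration and daily time out,
    events/hour for restlessness and indoor activity.  Post-event values are
    clipped back into the routine invariants (with a warning).
    """

    sleep_duration_s: tuple[float, float] = (0.0, 0.0)
    restlessness_rate: tuple[float, float] = (0.0, 0.0)
    time_out_s: tuple[float, float] = (0.0, 0.0)
    activity_rate: tuple[float, float] = (0.0, 0.0)

    def shift_at(self, which: str, event_day: int) -> float:
        shift, trend = getattr(self, which)
        return shift + trend * event_day


@dataclass
class SimulationSpec:
    """Full description of one simulated study arm."""

    event_type: EventType = EventType.COVID
    n_participants: int = 13
    days_pre: int = 66
    days_event: int = 66
    pre_start: dt.date = dt.date(2019, 3, 17)
    event_start: dt.date = dt.date(2020, 3, 17)
    routine: RoutineParams = field(default_factory=RoutineParams)
    routine_jitter: float = 0.05   # relative SD of per-participant parameter draws
    effect: EventEffect = field(default_factory=EventEffect)
    # marker-level generating coefficients: name -> (b0, b1, b2, b3)
    marker_truth: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    marker_noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    calendar: EventCalendar | None = None
    # explicit date lists (e.g. scattered smoke baseline days); when None the
    # periods are contiguous ranges from pre_start / event_start
    pre_dates: list[dt.date] | None = None
    event_dates: list[dt.date] | None = None

    def __post_init__(self) -> None:
        if self.days_pre < 1 or self.days_event < 1:
            raise ValueError("need at least one day on each side of the event")
        self.routine.validate()

    @property
    def t0(self) -> int:
        return self.days_pre

    def dates(self) -> list[dt.date]:
        if self.pre_dates is not None and self.event_dates is not None:
            return sorted(self.pre_dates) + sorted(self.event_dates)
        pre = [self.pre_start + dt.timedelta(days=i) for i in range(self.days_pre)]
        ev = [self.event_start + dt.timedelta(days=i) for i in range(self.days_event)]
        return pre + ev


# ---------------------------------------------------------------------------
# layout shared by all simulated homes


def default_layout() -> HomeLayout:
    """A six-area single-resident home: one motion sensor per area plus a
    second bedroom sensor, and one external door contact in the entry."""
    return HomeLayout(
        areas={
            "m_bed1": "bedroom", "m_bed2": "bedroom",
            "m_bath": "bathroom", "m_kitchen": "kitchen",
            "m_living": "living", "m_office": "office",
            "m_entry": "entry",
        },
        bedroom_areas=frozenset({"bedroom"}),
        external_doors=frozenset({"d_front"}),
        door_areas=frozenset({"entry"}),
    )


# ---------------------------------------------------------------------------
# event-stream simulation


def _clip_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _participant_routine(spec: SimulationSpec, rng: np.random.Generator) -> RoutineParams:
    """Sample one participant's routine around the population means."""
    r = spec.routine
    j = spec.routine_jitter
    out = dataclasses.replace(
        r,
        bedtime_mean=_clip_normal(rng, r.bedtime_mean, j * 60, 19 * 60, 24 * 60 - 1),
        wake_mean=_clip_normal(rng, r.wake_mean, j * 60, 4 * 60, 11 * 60 - 1),
        restlessness_rate=max(0.0, rng.normal(r.restlessness_rate, j * r.restlessness_rate)),
        outings_per_day=max(0.0, rng.normal(r.outings_per_day, j * r.outings_per_day)),
        outing_dur_mean=max(30.0, rng.normal(r.outing_dur_mean, j * r.outing_dur_mean)),
        activity_rate=max(1.0, rng.normal(r.activity_rate, j * r.activity_rate)),
        area_probs=dict(r.area_probs),
    )
    return out


_AREA_SENSOR = {
    "kitchen": "m_kitchen", "living": "m_living", "bathroom": "m_bath",
    "office": "m_office", "bedroom": "m_bed1", "entry": "m_entry",
}


def _motion(t: dt.datetime, area: str) -> SensorEvent:
    return SensorEvent(t, _AREA_SENSOR[area], SensorType.MOTION, "ON")


def simulate_home(
    spec: SimulationSpec, participant_index: int
) -> tuple[list[SensorEvent], pd.DataFrame]:
    """Simulate one home's event stream plus its ground-truth daily log.

    The log has one row per day with the true sleep interval, interruption
    time, restless-reading count, outings, and total time out — the oracle
    the marker-extraction state machines are tested against.

    A day whose routine is infeasible after clipping (e.g. no room left for
    an outing) is regenerated; after 100 retries the simulation aborts.
    """
    rng = np.random.default_rng([spec.seed, 1, participant_index])
    routine = _participant_routine(spec, rng)
    layout = default_layout()
    areas = list(routine.area_probs)
    probs = np.array([routine.area_probs[a] for a in areas])
    probs = probs / probs.sum()

    events: list[SensorEvent] = []
    log_rows: list[dict] = []
    dates = spec.dates()

    base_sleep_s = (routine.wake_mean + 24 * 60 - routine.bedtime_mean) * _MIN
    base_out_s = routine.outings_per_day * routine.outing_dur_mean * _MIN

    for day_i, date in enumerate(dates):
        in_event = day_i >= spec.days_pre
        e_idx = day_i - spec.days_pre
        # event-shifted drivers, clipped back into routine invariants
        sleep_target = base_sleep_s
        rest_rate = routine.restlessness_rate
        out_target = base_out_s
        act_rate = routine.activity_rate
        if in_event:
            sleep_target += spec.effect.shift_at("sleep_duration_s", e_idx)
            rest_rate += spec.effect.shift_at("restlessness_rate", e_idx)
            out_target += spec.effect.shift_at("time_out_s", e_idx)
            act_rate += spec.effect.shift_at("activity_rate", e_idx)
            clipped = (
                rest_rate < 0 or act_rate < 1.0 or out_target < 0
                or not (4 * _HR <= sleep_target <= 10 * _HR)
            )
            if clipped:
                warnings.warn(
                    f"day {date}: event effect clipped into routine invariants",
                    stacklevel=2,
                )
            rest_rate = max(0.0, rest_rate)
            act_rate = max(1.0, act_rate)
            out_target = max(0.0, out_target)
            sleep_target = float(np.clip(sleep_target, 4 * _HR, 10 * _HR))

        for attempt in range(101):
            day = _simulate_day(
                rng, routine, layout, areas, probs, date,
                sleep_target, rest_rate, out_target, act_rate,
            )
            if day is not None:
                break
        else:  # pragma: no cover - guarded by retry warning
            raise RuntimeError(f"infeasible routine on {date} after 100 retries")
        if attempt > 0:
            warnings.warn(f"day {date}: regenerated {attempt} time(s)", stacklevel=2)
        day_events, row = day
        events.extend(day_events)
        row["participant_index"] = participant_index
        row["day_index"] = day_i
        row["period"] = "event" if in_event else "nonevent"
        log_rows.append(row)

    events.sort(key=lambda e: e.timestamp)
    return events, pd.DataFrame(log_rows)


def _simulate_day(
    rng, routine, layout, areas, probs, date,
    sleep_target_s, rest_rate, out_target_s, act_rate,
):
    """One day's events: returns (events, ground-truth row) or None if infeasible."""
    midnight = dt.datetime.combine(date, dt.time(0, 0))

    # --- night sleep: clipped into the 21:00-07:00 detection window
    bed_min = _clip_normal(
        rng, routine.bedtime_mean, routine.bedtime_sd, 21 * 60 + 5, 23 * 60 + 55
    )
    bed = midnight + dt.timedelta(minutes=bed_min)
    wake = bed + dt.timedelta(seconds=_clip_normal(rng, sleep_target_s, routine.wake_sd * _MIN,
                                                   4 * _HR, 10 * _HR))
    latest_wake = midnight + dt.timedelta(days=1, hours=6, minutes=52)
    earliest_wake = midnight + dt.timedelta(days=1, hours=4, minutes=5)
    wake = min(max(wake, earliest_wake), latest_wake)

    ev: list[SensorEvent] = []
    ev.append(_motion(bed, "bedroom"))

    # optional mid-sleep interruption (bathroom visit)
    interruption = None
    if rng.random() < routine.interruption_prob:
        dur = dt.timedelta(
            minutes=_clip_normal(rng, routine.interruption_dur_mean,
                                 routine.interruption_dur_sd, 6, 60)
        )
        lo = bed + dt.timedelta(minutes=40)
        hi = wake - dt.timedelta(minutes=40) - dur
        if hi > lo:
            istart = lo + (hi - lo) * rng.random()
            interruption = (istart, istart + dur)
            ev.append(_motion(istart, "bathroom"))
            ev.append(_motion(istart + dt.timedelta(seconds=45), "bathroom"))
            ev.append(_motion(istart + dt.timedelta(seconds=95), "bathroom"))
            ev.append(_motion(istart + dur, "bedroom"))

    # restless bedroom readings, kept clear of sleep edges and the interruption
    sleep_hours = (wake - bed).total_seconds() / _HR
    n_rest = rng.poisson(rest_rate * sleep_hours)
    guard = dt.timedelta(minutes=6)
    restless_times: list[dt.datetime] = []
    for _ in range(n_rest):
        for _try in range(50):
            t = bed + dt.timedelta(
                seconds=float(rng.uniform(guard.total_seconds(),
                                          (wake - bed).total_seconds() - guard.total_seconds()))
            )
            if interruption and interruption[0] - dt.timedelta(minutes=2) <= t <= interruption[1] + guard:
                continue
            restless_times.append(t)
            break
    for t in restless_times:
        ev.append(_motion(t, "bedroom"))

    # morning: leave the bedroom (>=3 non-bedroom readings flip the state)
    for k, area in enumerate(["bathroom", "kitchen", "kitchen"]):
        ev.append(_motion(wake + dt.timedelta(seconds=40 + 50 * k), area))

    # --- daytime outings on this calendar day; daytime events start after the
    # sleep-detection window closes at 07:00 so they can never perturb the
    # previous night's state machine
    day_start = midnight + dt.timedelta(hours=7, minutes=5)
    day_end = midnight + dt.timedelta(minutes=bed_min) - dt.timedelta(minutes=35)
    outings: list[tuple[dt.datetime, dt.datetime]] = []
    n_out = min(int(rng.poisson(routine.outings_per_day)), 4)
    if n_out > 0 and out_target_s > 0:
        per = max(25 * _MIN, out_target_s / n_out)
        free = [(day_start, day_end)]
        for _ in range(n_out):
            dur = dt.timedelta(seconds=_clip_normal(rng, per, routine.outing_dur_sd * _MIN,
                                                    25 * _MIN, 6 * _HR))
            placed = False
            for _try in range(100):
                slot_i = int(rng.integers(len(free)))
                lo, hi = free[slot_i]
                if hi - lo < dur + dt.timedelta(minutes=20):
                    continue
                start = lo + (hi - lo - dur - dt.timedelta(minutes=10)) * rng.random()
                end = start + dur
                free[slot_i : slot_i + 1] = [
                    (lo, start - dt.timedelta(minutes=5)),
                    (end + dt.timedelta(minutes=5), hi),
                ]
                outings.append((start, end))
                placed = True
                break
            if not placed and not outings:
                return None  # infeasible day; regenerate
    outings.sort()
    for start, end in outings:
        ev.append(_motion(start - dt.timedelta(seconds=25), "entry"))
        ev.append(SensorEvent(start - dt.timedelta(seconds=10), "d_front", SensorType.DOOR, "OPEN"))
        ev.append(SensorEvent(start, "d_front", SensorType.DOOR, "CLOSE"))
        ev.append(SensorEvent(end, "d_front", SensorType.DOOR, "OPEN"))
        ev.append(SensorEvent(end + dt.timedelta(seconds=8), "d_front", SensorType.DOOR, "CLOSE"))
        ev.append(_motion(end + dt.timedelta(seconds=15), "entry"))
        ev.append(_motion(end + dt.timedelta(seconds=45), "living"))
        ev.append(_motion(end + dt.timedelta(seconds=75), "living"))

    # --- indoor activity while home & awake (non-bedroom, non-entry areas)
    def in_outing(t):
        return any(s - dt.timedelta(seconds=30) <= t <= e + dt.timedelta(seconds=90)
                   for s, e in outings)

    awake_s = (day_end - day_start).total_seconds() - sum(
        (e - s).total_seconds() for s, e in outings
    )
    n_act = rng.poisson(act_rate * max(awake_s, 0.0) / _HR)
    n_placed = 0
    for _ in range(n_act):
        for _try in range(50):
            t = day_start + dt.timedelta(
                seconds=float(rng.uniform(0, (day_end - day_start).total_seconds()))
            )
            if in_outing(t):
                continue
            ev.append(_motion(t, areas[int(rng.choice(len(areas), p=probs))]))
            n_placed += 1
            break

    # sparse uninformative background (light + temperature)
    for hour in (10, 16, 22):
        t = midnight + dt.timedelta(hours=hour)
        ev.append(SensorEvent(t, "m_living", SensorType.LIGHT, f"{rng.uniform(50, 300):.0f}"))
        ev.append(SensorEvent(t, "d_front", SensorType.TEMPERATURE, f"{rng.uniform(15, 25):.1f}"))

    row = {
        "date": date,
        "true_sleep_start": bed,
        "true_sleep_end": wake,
        "true_sleep_duration_s": (wake - bed).total_seconds(),
        "true_interruption_s": (
            (interruption[1] - interruption[0]).total_seconds() if interruption else 0.0
        ),
        "true_restless_count": len(restless_times),
        "true_n_outings": len(outings),
        "true_time_out_s": sum((e - s).total_seconds() for s, e in outings),
        "true_activity_count": n_placed,
    }
    return ev, row


def simulate_covariates(spec: SimulationSpec) -> list[Participant]:
    """Participant covariates drawn to resemble the study cohorts."""
    rng = np.random.default_rng([spec.seed, 2])
    out = []
    for i in range(spec.n_participants):
        if spec.event_type is EventType.COVID:
            age = _clip_normal(rng, 84, 6, 70, 99) if i >= 2 else _clip_normal(rng, 24, 5, 20, 34)
            gender = "female" if rng.random() < 0.69 else "male"
            edu = _clip_normal(rng, 17, 2, 10, 22)
        else:
            age = _clip_normal(rng, 91, 6, 75, 104)
            u = rng.random()
            gender = "female" if u < 0.46 else ("male" if u < 0.71 else "unreported")
            edu = _clip_normal(rng, 17.5, 2.4, 10, 22)
        out.append(
            Participant(f"p{i:02d}", round(age, 1), gender, round(edu, 1))
        )
    return out


# ---------------------------------------------------------------------------
# marker-level simulation


def simulate_marker_series(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Daily marker values with known segmented-trend structure.

    For each marker with generating coefficients ``(b0, b1, b2, b3)``:
    ``X_t = b0 + b1*t`` on pre-event days and
    ``X_t = b0 + b1*t + b2 + b3*(t - t0)`` on event days, plus i.i.d.
    Gaussian noise with the marker's stated SD.  All participants share the
    generating coefficients; noise is independent per participant-day.

    Returns the long-format table and the truth dict
    ``{marker: {"beta": (b0..b3), "sd": sd}}``.
    """
    if not spec.marker_truth:
        raise ValueError("spec has no marker_truth coefficients")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t = np.arange(spec.days_pre + spec.days_event)
    d_event = (t >= spec.t0).astype(float)
    dates = spec.dates()
    frames = []
    for p in range(spec.n_participants):
        row = {"participant_id": f"p{p:02d}", "t": t, "date": dates,
               "period": np.where(d_event > 0, "event", "nonevent")}
        for name, (b0, b1, b2, b3) in spec.marker_truth.items():
            mean = b0 + b1 * t + d_event * (b2 + b3 * (t - spec.t0))
            sd = spec.marker_noise_sd.get(name, 0.0)
            noise = rng.normal(0.0, sd, size=t.size) if sd > 0 else 0.0
            row[name] = mean + noise
        frames.append(pd.DataFrame(row))
    df = pd.concat(frames, ignore_index=True)
    truth = {
        name: {"beta": tuple(b), "sd": spec.marker_noise_sd.get(name, 0.0)}
        for name, b in spec.marker_truth.items()
    }
    return df, truth


# ---------------------------------------------------------------------------
# presets


def covid_preset(
    seed: int = 0, days_pre: int = 66, days_event: int = 66
) -> SimulationSpec:
    """Pandemic-lockdown study arm: 13 participants, 66 days per side.

    Marker-generating coefficients are the published total-row
    interrupted-time-series estimates for this condition (initial level,
    pre-event trend, immediate impact, long-term trend); e.g. time out starts
    at 21,500 s/day and drops by 13,700 s on the first lockdown day.

    Truncated arms (``days_pre < 66``) keep the pre period abutting the
    interruption: pre days are the last ``days_pre`` days of the
    season-matched baseline window, event days the first ``days_event`` days
    of the lockdown.
    """
    calendar = EventCalendar(
        event_type=EventType.COVID,
        lockdown_start=dt.date(2020, 3, 17),
        lockdown_end=dt.date(2020, 5, 21),
    )
    if not 1 <= days_pre <= 66 or not 1 <= days_event <= 66:
        raise ValueError("covid preset supports 1-66 days per side")
    pre_start = dt.date(2019, 5, 21) - dt.timedelta(days=days_pre - 1)
    effect = EventEffect(
        sleep_duration_s=(22.0, -1.96),
        restlessness_rate=(1.5, 0.0),
        time_out_s=(-13_700.0, 26.0),
        activity_rate=(-6.0, 0.0),
    )
    # routine baselines consistent with the encoded initial levels:
    # ~28,900 s nominal sleep, ~21,500 s/day nominal time out
    routine = RoutineParams(
        bedtime_mean=22 * 60 + 10, wake_mean=6 * 60 + 12,
        outings_per_day=2.5, outing_dur_mean=143.0,
    )
    return SimulationSpec(
        event_type=EventType.COVID,
        n_participants=13,
        days_pre=days_pre,
        days_event=days_event,
        pre_start=pre_start,
        event_start=dt.date(2020, 3, 17),
        routine=routine,
        effect=effect,
        marker_truth={
            "sleep_duration": (28_900.0, 4.00, 22.00, -1.96),
            "restlessness": (-0.09, -6.65e-05, 0.762, 0.0),
            "sleep_efficiency": (0.79, 0.0, 0.0, 0.0),
            "activity_level": (0.54, 0.0, -0.21, 0.0),
            "time_out": (21_500.0, -6.00, -13_700.0, 26.00),
        },
        marker_noise_sd={
            "sleep_duration": 1800.0,
            "restlessness": 0.5,
            "sleep_efficiency": 0.05,
            "activity_level": 0.30,
            "time_out": 3600.0,  # one hour of day-to-day noise
        },
        seed=seed,
        calendar=calendar,
    )


def _smoke_aqi(days_pre: int, days_event: int) -> pd.Series:
    """An August AQI series with one smoke run of ``days_event`` days >100
    and at least ``days_pre`` good-air days (<=50) in the same month."""
    year = 2020
    month_days = 31
    event_first = 12
    vals = {}
    for d in range(1, month_days + 1):
        date = dt.date(year, 8, d)
        if event_first <= d < event_first + days_event:
            vals[date] = 150 + 5 * ((d - event_first) % 4)
        else:
            vals[date] = 35 + (d % 3) * 5  # 35-45: good air
    return pd.Series(vals, name="aqi")


def smoke_preset(
    seed: int = 0, days_pre: int = 14, days_event: int = 14
) -> SimulationSpec:
    """Wildfire-smoke study arm: 28 participants, configurable window length.

    The preset generates its own AQI series (one >100 run of
    ``days_event`` consecutive days, matched good-air days <=50 in the same
    month) so window selection is testable without any download.
    """
    if days_event + days_pre > 29:
        raise ValueError("smoke preset windows must fit in one month (<=29 days total)")
    aqi = _smoke_aqi(days_pre, days_event)
    calendar = EventCalendar(event_type=EventType.SMOKE, aqi=aqi)
    window = _markers.select_windows(EventType.SMOKE, calendar, list(aqi.index))
    nonevent = sorted(window.nonevent_dates)[:days_pre]
    event = sorted(window.event_dates)
    effect = EventEffect(
        sleep_duration_s=(-1652.49, -1.95),
        restlessness_rate=(-0.4, 0.0),
        time_out_s=(1969.0, -2.0),
        activity_rate=(-2.0, 0.0),
    )
    # ~30,840 s nominal sleep, ~26,180 s/day nominal time out
    routine = RoutineParams(
        bedtime_mean=21 * 60 + 50, wake_mean=6 * 60 + 24,
        outings_per_day=2.5, outing_dur_mean=174.5,
    )
    return SimulationSpec(
        event_type=EventType.SMOKE,
        n_participants=28,
        days_pre=len(nonevent),
        days_event=len(event),
        pre_start=nonevent[0],
        event_start=event[0],
        pre_dates=nonevent,
        event_dates=event,
        routine=routine,
        effect=effect,
        marker_truth={
            "sleep_duration": (30_860.0, -0.17, -1652.49, -1.95),
            "restlessness": (0.15, 0.0, -0.18, 0.0),
            "sleep_efficiency": (0.92, 0.0, -0.06, 0.0),
            "activity_level": (0.07, 0.0, -0.08, 0.0),
            "time_out": (26_180.0, 0.86, 1969.0, -2.00),
        },
        marker_noise_sd={
            "sleep_duration": 1800.0,
            "restlessness": 0.5,
            "sleep_efficiency": 0.05,
            "activity_level": 0.30,
            "time_out": 3600.0,
        },
        seed=seed,
        calendar=calendar,
    )


# ---------------------------------------------------------------------------
# spec (de)serialization


def spec_to_dict(spec: SimulationSpec) -> dict:
    d = {
        "event_type": spec.event_type.value,
        "n_participants": spec.n_participants,
        "days_pre": spec.days_pre,
        "days_event": spec.days_event,
        "pre_start": spec.pre_start.isoformat(),
        "event_start": spec.event_start.isoformat(),
        "routine": asdict(spec.routine),
        "routine_jitter": spec.routine_jitter,
        "effect": asdict(spec.effect),
        "marker_truth": {k: list(v) for k, v in spec.marker_truth.items()},
        "marker_noise_sd": dict(spec.marker_noise_sd),
        "seed": spec.seed,
    }
    if spec.pre_dates is not None and spec.event_dates is not None:
        d["pre_dates"] = [x.isoformat() for x in spec.pre_dates]
        d["event_dates"] = [x.isoformat() for x in spec.event_dates]
    if spec.calendar is not None:
        if spec.calendar.event_type is EventType.COVID:
            d["calendar"] = {
                "event_type": "covid",
                "lockdown_start": spec.calendar.lockdown_start.isoformat(),
                "lockdown_end": spec.calendar.lockdown_end.isoformat(),
            }
        else:
            d["calendar"] = {
                "event_type": "smoke",
                "aqi": [
                    {"date": k.isoformat(), "aqi": int(v)}
                    for k, v in spec.calendar.aqi.items()
                ],
            }
    return d


def spec_from_dict(d: dict) -> SimulationSpec:
    calendar = None
    if "calendar" in d:
        c = d["calendar"]
        if c["event_type"] == "covid":
            calendar = EventCalendar(
                EventType.COVID,
                lockdown_start=dt.date.fromisoformat(c["lockdown_start"]),
                lockdown_end=dt.date.fromisoformat(c["lockdown_end"]),
            )
        else:
            calendar = EventCalendar(
                EventType.SMOKE,
                aqi=pd.Series(
                    {dt.date.fromisoformat(r["date"]): int(r["aqi"]) for r in c["aqi"]},
                    name="aqi",
                ),
            )
    eff = d.get("effect", {})
    return SimulationSpec(
        event_type=EventType(d["event_type"]),
        n_participants=int(d["n_participants"]),
        days_pre=int(d["days_pre"]),
        days_event=int(d["days_event"]),
        pre_start=dt.date.fromisoformat(d["pre_start"]),
        event_start=dt.date.fromisoformat(d["event_start"]),
        routine=RoutineParams(**d.get("routine", {})),
        routine_jitter=float(d.get("routine_jitter", 0.05)),
        effect=EventEffect(**{k: tuple(v) for k, v in eff.items()}),
        marker_truth={k: tuple(v) for k, v in d.get("marker_truth", {}).items()},
        marker_noise_sd={k: float(v) for k, v in d.get("marker_noise_sd", {}).items()},
        seed=int(d.get("seed", 0)),
        calendar=calendar,
        pre_dates=(
            [dt.date.fromisoformat(x) for x in d["pre_dates"]]
            if "pre_dates" in d else None
        ),
        event_dates=(
            [dt.date.fromisoformat(x) for x in d["event_dates"]]
            if "event_dates" in d else None
        ),
    )


def write_spec(spec: SimulationSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def read_spec(path: str | Path) -> SimulationSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
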