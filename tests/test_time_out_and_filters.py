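"""Out-of-home detection, daily marker assembly, validity filters,
normalization and window selection."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest

from ambient_phenotype.events import EventCalendar, EventType
from ambient_phenotype.markers import (
    StudyWindow,
    compute_daily_markers,
    detect_time_out,
    filter_days,
    normalize_person,
    select_windows,
)

from conftest import NIGHT, at, door, motion

DAY = NIGHT  # detect_time_out works on the calendar day


def _interior_run(h, m):
    return [
        motion(at(0, h, m), "mk"),
        motion(at(0, h, m + 1), "ml"),
        motion(at(0, h, m + 2), "mk"),
    ]


def test_door_then_silence_then_interior_run(layout):
    """Door close at 09:00, two hours of silence, interior run at 11:00:
    out of home 09:00-11:00 (7,200 s)."""
    ev = (
        _interior_run(8, 30)
        + [door(at(0, 8, 59, 50), "OPEN"), door(at(0, 9, 0), "CLOSE")]
        + _interior_run(11, 0)
    )
    outs = detect_time_out(ev, layout, DAY)
    assert len(outs) == 1
    start, end, open_ended = outs[0]
    assert (start, end) == (at(0, 9, 0), at(0, 11, 0))
    assert (end - start).total_seconds() == 7_200
    assert not open_ended


def test_interior_silence_is_not_an_outing(layout):
    """A 25-minute silence whose last readings came from an interior area
    fails the location condition."""
    ev = _interior_run(9, 0) + _interior_run(9, 30)
    assert detect_time_out(ev, layout, DAY) == []


def test_twenty_minute_gap_is_strict(layout):
    """The rule is strictly more than 20 minutes of silence."""
    exactly = (
        [door(at(0, 9, 0), "CLOSE")] + _interior_run(9, 20)
    )
    assert detect_time_out(exactly, layout, DAY) == []
    over = [door(at(0, 9, 0), "CLOSE")] + _interior_run(9, 21)
    assert len(detect_time_out(over, layout, DAY)) == 1


def test_door_area_motion_counts_as_door_reading(layout):
    ev = [motion(at(0, 9, 0), "me")] + _interior_run(10, 0)
    outs = detect_time_out(ev, layout, DAY)
    assert outs and outs[0][0] == at(0, 9, 0)


def test_outing_needs_three_interior_readings_to_end(layout):
    """Two interior readings do not end the episode; it runs to the next
    full interior run."""
    ev = (
        [door(at(0, 9, 0), "CLOSE")]
        + [motion(at(0, 10, 0), "mk"), motion(at(0, 10, 1), "ml")]
        + [door(at(0, 10, 2), "OPEN")]  # breaks the run
        + _interior_run(12, 0)
    )
    outs = detect_time_out(ev, layout, DAY)
    assert outs[0][1] == at(0, 12, 0)


def test_day_ending_mid_outing_is_clipped_and_flagged(layout):
    ev = _interior_run(20, 0) + [door(at(0, 21, 0), "CLOSE")]
    outs = detect_time_out(ev, layout, DAY)
    assert outs == [(at(0, 21, 0), at(1, 0, 0), True)]


def test_nighttime_bedroom_gap_is_sleep_not_absence(layout):
    """While asleep, a long reading-free gap must not be classified as out of
    the home even if the last reading was near the door."""
    asleep = [(at(0, 1, 0), at(0, 6, 0))]
    ev = [door(at(0, 1, 30), "CLOSE")] + _interior_run(6, 30)
    assert detect_time_out(ev, layout, DAY, asleep_intervals=asleep) == []
    # the same stream while awake is an outing
    assert len(detect_time_out(ev, layout, DAY)) == 1


# --- daily markers ---------------------------------------------------------


def test_unbroken_sleep_efficiency_one(layout):
    ev = [motion(at(0, 22, 0), "mb"), motion(at(1, 6, 0), "mb")]
    row = compute_daily_markers(ev, layout, "p0", NIGHT)
    assert row["sleep_duration"] == 8 * 3600
    assert row["sleep_efficiency"] == pytest.approx(1.0)
    assert row["restlessness_raw"] == 0


def test_interrupted_sleep_efficiency(layout):
    """An 8-hour span containing a 1-hour awake interruption has efficiency
    7/8."""
    ev = [
        motion(at(0, 22, 0), "mb"),
        motion(at(1, 2, 0), "mk"),
        motion(at(1, 2, 10), "mk"),
        motion(at(1, 2, 20), "mk"),
        motion(at(1, 3, 0), "mb"),
        motion(at(1, 6, 0), "mb"),
    ]
    row = compute_daily_markers(ev, layout, "p0", NIGHT)
    assert row["sleep_duration"] == 8 * 3600
    assert row["sleep_efficiency"] == pytest.approx(7 / 8)


def test_no_sleep_day_keeps_row_with_missing_efficiency(layout):
    ev = _interior_run(12, 0)
    row = compute_daily_markers(ev, layout, "p0", NIGHT)
    assert row["sleep_duration"] == 0
    assert np.isnan(row["sleep_efficiency"])
    assert row["valid"]  # day retained


def test_zero_event_day_flagged_sensor_failure(layout):
    row = compute_daily_markers([], layout, "p0", NIGHT)
    assert not row["valid"]
    assert row["invalid_reason"] == "sensor_failure"


def test_time_out_plus_home_bounded(layout):
    ev = (
        [door(at(0, 8, 0), "CLOSE")]
        + _interior_run(12, 0)
        + [door(at(0, 14, 0), "CLOSE")]
        + _interior_run(20, 0)
    )
    row = compute_daily_markers(ev, layout, "p0", NIGHT)
    assert 0 <= row["time_out"] <= 86_400


# --- filters ----------------------------------------------------------------


def _marker_rows(time_out_values):
    return pd.DataFrame(
        {
            "participant_id": "p0",
            "date": [dt.date(2020, 3, 1 + i) for i in range(len(time_out_values))],
            "sleep_duration": 28_800.0,
            "sleep_efficiency": 0.9,
            "restlessness_raw": 2.0,
            "time_out": time_out_values,
            "activity_raw": 10.0,
            "valid": True,
            "invalid_reason": "none",
        }
    )


def test_half_day_threshold_is_strict():
    """Out 'more than half the day': 43,200 s is valid, 43,201 s is not."""
    df = _marker_rows([43_200.0, 43_201.0])
    out = filter_days(df)
    assert list(out["date"]) == [dt.date(2020, 3, 1)]


def test_filter_days_restricts_to_window():
    df = _marker_rows([0.0, 0.0, 0.0, 0.0])
    window = StudyWindow(
        EventType.COVID,
        nonevent_dates=[dt.date(2020, 3, 1)],
        event_dates=[dt.date(2020, 3, 3)],
    )
    out = filter_days(df, window)
    assert set(out["date"]) == {dt.date(2020, 3, 1), dt.date(2020, 3, 3)}


# --- normalization ----------------------------------------------------------


def test_zscore_two_days_closed_form():
    """Counts {10, 20} z-score to -1/+1 under the population SD (mean 15,
    sigma 5) — the standard-scaler convention."""
    df = _marker_rows([0.0, 0.0])
    df["activity_raw"] = [10.0, 20.0]
    df["restlessness_raw"] = [10.0, 20.0]
    out = normalize_person(df)
    assert out["activity_level"].to_numpy() == pytest.approx([-1.0, 1.0])
    assert out["restlessness"].to_numpy() == pytest.approx([-1.0, 1.0])


def test_zero_variance_normalizes_to_zero_with_warning():
    df = _marker_rows([0.0, 0.0, 0.0])
    with pytest.warns(UserWarning, match="zero variance"):
        out = normalize_person(df)
    assert (out["activity_level"] == 0).all()


def test_normalized_markers_standardized_over_valid_days():
    rng = np.random.default_rng(0)
    df = _marker_rows(list(np.zeros(30)))
    df["activity_raw"] = rng.uniform(5, 25, 30)
    df["restlessness_raw"] = rng.poisson(4, 30).astype(float)
    out = normalize_person(df)
    assert out["activity_level"].mean() == pytest.approx(0, abs=1e-12)
    assert out["activity_level"].std(ddof=0) == pytest.approx(1, abs=1e-12)


# --- window selection -------------------------------------------------------


def _aqi(values, year=2020, month=8):
    return pd.Series(
        {dt.date(year, month, i + 1): v for i, v in enumerate(values)}, name="aqi"
    )


def test_smoke_window_hand_traced():
    """AQI [40,40,150,160,45,30]: days 3-4 are the smoke run, and the two
    nearest good-air days in the month are its baseline."""
    aqi = _aqi([40, 40, 150, 160, 45, 30])
    cal = EventCalendar(EventType.SMOKE, aqi=aqi)
    w = select_windows(EventType.SMOKE, cal, list(aqi.index))
    assert w.event_dates == [dt.date(2020, 8, 3), dt.date(2020, 8, 4)]
    assert len(w.nonevent_dates) == 2
    assert set(w.nonevent_dates) <= {
        dt.date(2020, 8, 1), dt.date(2020, 8, 2),
        dt.date(2020, 8, 5), dt.date(2020, 8, 6),
    }
    # nearest-by-date tie-break picks the days adjacent to the run
    assert w.nonevent_dates == [dt.date(2020, 8, 2), dt.date(2020, 8, 5)]


def test_isolated_high_aqi_day_is_no_event():
    aqi = _aqi([40, 150, 45, 40])
    cal = EventCalendar(EventType.SMOKE, aqi=aqi)
    with pytest.warns(UserWarning, match="no AQI run"):
        w = select_windows(EventType.SMOKE, cal, list(aqi.index))
    assert w.event_dates == [] and w.nonevent_dates == []


def test_insufficient_baseline_days_warns():
    aqi = _aqi([150, 150, 150, 150, 40])
    cal = EventCalendar(EventType.SMOKE, aqi=aqi)
    with pytest.warns(UserWarning, match="baseline day"):
        w = select_windows(EventType.SMOKE, cal, list(aqi.index))
    assert len(w.event_dates) == 4 and len(w.nonevent_dates) == 1


def test_covid_window_66_days():
    """The 2020-03-17..2020-05-21 lockdown spans 66 calendar days, matched by
    the same span one year earlier."""
    cal = EventCalendar(
        EventType.COVID,
        lockdown_start=dt.date(2020, 3, 17),
        lockdown_end=dt.date(2020, 5, 21),
    )
    avail = [dt.date(2019, 1, 1) + dt.timedelta(days=i) for i in range(700)]
    w = select_windows(EventType.COVID, cal, avail)
    assert len(w.event_dates) == 66
    assert len(w.nonevent_dates) == 66
    assert w.t0 == 66
    assert w.nonevent_dates[0] == dt.date(2019, 3, 17)
    assert w.event_dates[-1] == dt.date(2020, 5, 21)
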