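"""Simulator: determinism, ground-truth consistency, preset encoding,
marker-series structure, and convergence of simulated behavior to the
generating parameters."""

import dataclasses
import datetime as dt
import warnings

import numpy as np
import pytest
from scipy import stats

import ambient_phenotype as ap
from ambient_phenotype.events import SensorType
from ambient_phenotype.synthetic import (
    RoutineParams,
    read_spec,
    spec_from_dict,
    spec_to_dict,
    write_spec,
)


def small_covid(seed=0, **kw):
    spec = ap.covid_preset(seed=seed, days_pre=kw.pop("days_pre", 3),
                           days_event=kw.pop("days_event", 3))
    return dataclasses.replace(spec, n_participants=1, **kw)


def test_quiet_sleeper_has_silent_nights():
    """With restlessness rate 0, no interruptions and no outings, the only
    motion between bedtime and wake is the bed/wake transition pair."""
    routine = RoutineParams(
        restlessness_rate=0.0, interruption_prob=0.0, outings_per_day=0.0
    )
    spec = dataclasses.replace(
        small_covid(), routine=routine, days_pre=2, days_event=1,
        effect=ap.EventEffect(),
    )
    ev, log = ap.simulate_home(spec, 0)
    for _, row in log.iterrows():
        bed, wake = row["true_sleep_start"], row["true_sleep_end"]
        inside = [
            e for e in ev
            if e.sensor_type is SensorType.MOTION and bed < e.timestamp < wake
        ]
        assert inside == []
        assert row["true_restless_count"] == 0
        assert row["true_time_out_s"] == 0


def test_ground_truth_time_out_matches_emitted_outings():
    spec = small_covid(seed=5)
    ev, log = ap.simulate_home(spec, 0)
    for _, row in log.iterrows():
        day = row["date"]
        opens = [
            e for e in ev
            if e.sensor_type is SensorType.DOOR and e.timestamp.date() == day
        ]
        # each outing is bracketed by exactly two OPEN/CLOSE pairs
        assert len(opens) == 4 * row["true_n_outings"]
        assert row["true_time_out_s"] >= 25 * 60 * row["true_n_outings"]


def test_same_seed_identical_different_seed_differs():
    a1, _ = ap.simulate_home(small_covid(seed=11), 0)
    a2, _ = ap.simulate_home(small_covid(seed=11), 0)
    b, _ = ap.simulate_home(small_covid(seed=12), 0)
    assert a1 == a2
    assert a1 != b


def test_marker_series_deterministic_and_noise_free_is_piecewise_linear():
    spec = ap.covid_preset()
    quiet = dataclasses.replace(spec, marker_noise_sd={})
    df, truth = ap.simulate_marker_series(quiet, seed=3)
    b0, b1, b2, b3 = truth["time_out"]["beta"]
    t = df["t"].to_numpy()
    expected = b0 + b1 * t + (t >= 66) * (b2 + b3 * (t - 66))
    assert df["time_out"].to_numpy() == pytest.approx(expected)
    # zero event terms collapse to one line
    one_line = dataclasses.replace(
        quiet, marker_truth={"m": (5.0, 0.25, 0.0, 0.0)}
    )
    df2, _ = ap.simulate_marker_series(one_line, seed=3)
    assert df2["m"].to_numpy() == pytest.approx(5.0 + 0.25 * df2["t"].to_numpy())


def test_covid_preset_encodes_published_time_out_drop():
    """Noise-free covid series drop by exactly 13,700 s at the interruption
    day (t0 = 66)."""
    quiet = dataclasses.replace(ap.covid_preset(), marker_noise_sd={})
    df, _ = ap.simulate_marker_series(quiet, seed=0)
    one = df[df["participant_id"] == "p00"].set_index("t")["time_out"]
    jump = one[66] - (one[65] + (one[65] - one[64]))  # observed minus continued line
    assert jump == pytest.approx(-13_700.0)


def test_preset_initial_levels():
    assert ap.covid_preset().marker_truth["time_out"][0] == 21_500.0
    assert ap.smoke_preset().marker_truth["sleep_duration"][0] == 30_860.0


def test_presets_roundtrip_through_config(tmp_path):
    for spec in (ap.covid_preset(seed=4), ap.smoke_preset(seed=4)):
        p = tmp_path / "spec.yaml"
        write_spec(spec, p)
        back = read_spec(p)
        assert spec_to_dict(back) == spec_to_dict(spec)


def test_smoke_preset_aqi_satisfies_window_rule():
    spec = ap.smoke_preset()
    aqi = spec.calendar.aqi
    event = set(spec.event_dates)
    # >=2 consecutive days over 100
    assert len(event) >= 2
    assert all(aqi[d] > 100 for d in event)
    # matched baseline days are good air in the same month
    assert all(aqi[d] <= 50 for d in spec.pre_dates)
    assert {d.month for d in spec.pre_dates} == {d.month for d in spec.event_dates}
    assert len(spec.pre_dates) == len(spec.event_dates)


def test_event_effect_is_visible_in_ground_truth():
    """The covid preset's -13,700 s immediate time-out shift moves the
    simulated homes' mean event-period time out well below baseline."""
    spec = dataclasses.replace(
        ap.covid_preset(seed=21, days_pre=10, days_event=10), n_participants=3
    )
    logs = []
    for i in range(3):
        _, log = ap.simulate_home(spec, i)
        logs.append(log)
    import pandas as pd

    log = pd.concat(logs)
    pre = log[log["period"] == "nonevent"]["true_time_out_s"].mean()
    post = log[log["period"] == "event"]["true_time_out_s"].mean()
    assert post < pre - 5_000


def test_marker_series_mean_converges_to_generating_line():
    """Law of large numbers at 1,000 days: the mean deviation of the series
    from the generating segments is within 3 standard errors of zero."""
    spec = dataclasses.replace(
        ap.covid_preset(), days_pre=500, days_event=500, n_participants=1
    )
    df, truth = ap.simulate_marker_series(spec, seed=9)
    b0, b1, b2, b3 = truth["time_out"]["beta"]
    sd = truth["time_out"]["sd"]
    t = df["t"].to_numpy()
    resid = df["time_out"].to_numpy() - (
        b0 + b1 * t + (t >= 500) * (b2 + b3 * (t - 500))
    )
    se = sd / np.sqrt(len(resid))
    assert abs(resid.mean()) < 3 * se


def test_home_sim_restlessness_converges_to_rate():
    """Mean nightly restless-reading count over 1,000 nights matches the
    Poisson rate times hours asleep within 3 standard errors."""
    routine = RoutineParams(restlessness_rate=1.2, interruption_prob=0.0,
                            outings_per_day=0.0)
    spec = dataclasses.replace(
        ap.covid_preset(seed=13, days_pre=66, days_event=66),
        routine=routine, routine_jitter=0.0, n_participants=1,
        effect=ap.EventEffect(),
    )
    # 1,000 nights stitched from repeated arms with distinct seeds
    counts, expected = [], []
    for s in range(8):
        _, log = ap.simulate_home(dataclasses.replace(spec, seed=s), 0)
        counts.extend(log["true_restless_count"])
        expected.extend(1.2 * log["true_sleep_duration_s"] / 3600.0)
    counts, expected = np.array(counts[:1000]), np.array(expected[:1000])
    se = np.sqrt(expected.mean() / len(counts))  # Poisson SE of the mean
    assert abs(counts.mean() - expected.mean()) < 3 * se


def test_infeasible_routine_parameters_rejected():
    with pytest.raises(ValueError):
        RoutineParams(bedtime_mean=18 * 60).validate()
    with pytest.raises(ValueError):
        RoutineParams(restlessness_rate=-1).validate()
    with pytest.raises(ValueError):
        RoutineParams(interruption_prob=1.5).validate()
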