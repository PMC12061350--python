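"""Phenotype clustering and event/nonevent separability."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ambient_phenotype.events import EventType
from ambient_phenotype.markers import MARKER_NAMES, StudyWindow
from ambient_phenotype.phenotype import (
    classify_days,
    cluster_phenotypes,
    participant_deltas,
)


def _window(n_pre=4, n_event=4):
    return StudyWindow(
        EventType.SMOKE,
        nonevent_dates=[dt.date(2020, 8, 1 + i) for i in range(n_pre)],
        event_dates=[dt.date(2020, 8, 15 + i) for i in range(n_event)],
    )


def _table(rows):
    df = pd.DataFrame(rows)
    df.setdefault = None
    if "valid" not in df:
        df["valid"] = True
    return df


def _day(pid, date, **markers):
    row = {
        "participant_id": pid,
        "date": date,
        "sleep_duration": 28_800.0,
        "sleep_efficiency": 0.9,
        "restlessness": 0.0,
        "time_out": 3_600.0,
        "activity_level": 0.0,
        "valid": True,
    }
    row.update(markers)
    return row


def test_identical_periods_give_zero_delta():
    w = _window()
    rows = [_day("p0", d) for d in w.nonevent_dates + w.event_dates]
    deltas = participant_deltas(_table(rows), w)
    assert (deltas.loc["p0"] == 0).all()


def test_deltas_hand_computed_toy_table():
    """Four-day toy table: delta equals the brute-force difference of period
    means."""
    w = _window(n_pre=2, n_event=2)
    rows = [
        _day("p0", w.nonevent_dates[0], time_out=1000.0, restlessness=0.5),
        _day("p0", w.nonevent_dates[1], time_out=3000.0, restlessness=1.5),
        _day("p0", w.event_dates[0], time_out=6000.0, restlessness=0.0),
        _day("p0", w.event_dates[1], time_out=8000.0, restlessness=-1.0),
    ]
    deltas = participant_deltas(_table(rows), w)
    assert deltas.loc["p0", "time_out"] == pytest.approx((6000 + 8000) / 2 - (1000 + 3000) / 2)
    assert deltas.loc["p0", "restlessness"] == pytest.approx(-0.5 - 1.0)


def test_hours_scale_delta_example():
    """Event mean 2.17 h vs nonevent 5.97 h gives a -3.80 h delta."""
    w = _window(n_pre=1, n_event=1)
    rows = [
        _day("p0", w.nonevent_dates[0], time_out=5.97 * 3600),
        _day("p0", w.event_dates[0], time_out=2.17 * 3600),
    ]
    deltas = participant_deltas(_table(rows), w)
    assert deltas.loc["p0", "time_out"] / 3600 == pytest.approx(-3.80)


def test_participant_missing_period_excluded_with_warning():
    w = _window(n_pre=2, n_event=2)
    rows = [_day("p0", d) for d in w.nonevent_dates + w.event_dates]
    rows += [_day("p1", d) for d in w.nonevent_dates]  # no event days
    with pytest.warns(UserWarning, match="p1.*missing a period"):
        deltas = participant_deltas(_table(rows), w)
    assert list(deltas.index) == ["p0"]


# --- clustering -------------------------------------------------------------


def _blobs(seed=0, per_blob=6, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = np.array(
        [
            [-3.0, 0.0, 2.0, -1.0, 0.5],
            [3.0, 1.0, -2.0, 1.0, -0.5],
            [0.0, -4.0, 0.0, 4.0, 3.0],
        ]
    )
    rows, truth = [], []
    for b, c in enumerate(centers):
        for i in range(per_blob):
            rows.append(c + rng.normal(0, spread, 5))
            truth.append(b)
    deltas = pd.DataFrame(
        rows,
        columns=list(MARKER_NAMES),
        index=[f"p{i:02d}" for i in range(len(rows))],
    )
    return deltas, np.array(truth)


def test_well_separated_blobs_recovered_exactly():
    deltas, truth = _blobs()
    res = cluster_phenotypes(deltas, k=3, seed=0)
    labels = np.array([res.assignments[p] for p in deltas.index])
    # same partition up to label permutation
    for b in range(3):
        assert len(set(labels[truth == b])) == 1
    assert sorted(res.sizes) == [6, 6, 6]
    assert sum(res.sizes) == len(deltas)


def test_k1_single_cluster():
    deltas, _ = _blobs()
    res = cluster_phenotypes(deltas, k=1, seed=0)
    assert res.sizes == [len(deltas)]


def test_clustering_deterministic_under_seed():
    deltas, _ = _blobs(seed=3, spread=1.0)
    a = cluster_phenotypes(deltas, k=3, seed=7)
    b = cluster_phenotypes(deltas, k=3, seed=7)
    assert a.assignments == b.assignments
    assert a.inertia == b.inertia


def test_cluster_stats_flag_real_shifts():
    deltas, truth = _blobs(per_blob=8, spread=0.1)
    res = cluster_phenotypes(deltas, k=3, seed=0)
    # in each cluster the first marker's mean delta is far from zero except
    # where its centroid is at zero
    for c in range(3):
        mean, p = res.cluster_stats[c][MARKER_NAMES[1]]
        if abs(mean) > 1:
            assert p < 0.01


def test_fewer_participants_than_k_rejected():
    deltas, _ = _blobs(per_blob=1)  # 3 rows
    with pytest.raises(ValueError, match="at least k"):
        cluster_phenotypes(deltas.iloc[:2], k=3)


# --- classification ---------------------------------------------------------


def _labeled_days(n_per=60, sep=0.0, seed=0):
    """Four labeled groups of days; ``sep`` shifts event-day features."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for etype in ("covid", "smoke"):
        for period in ("nonevent", "event"):
            shift = sep if period == "event" else 0.0
            for i in range(n_per):
                rows.append(
                    {
                        "sleep_duration": rng.normal(28_800 + shift * 4000, 1500),
                        "sleep_efficiency": rng.normal(0.9 - shift * 0.2, 0.03),
                        "restlessness": rng.normal(shift, 1.0),
                        "time_out": rng.normal(20_000 - shift * 10_000, 3000),
                        "activity_level": rng.normal(-shift, 1.0),
                    }
                )
                labels.append(f"{etype}_{period}")
    return pd.DataFrame(rows), pd.Series(labels)


def test_shuffled_labels_give_chance_accuracy():
    X, y = _labeled_days(sep=1.0, seed=1)
    y_shuffled = pd.Series(
        np.random.default_rng(5).permutation(y.to_numpy()), index=y.index
    )
    rep = classify_days(X, y_shuffled, task="event_vs_nonevent", seed=0)
    # no better than chance: the binomial test should not reject
    assert rep.p_value > 0.01
    assert abs(rep.accuracy - 0.5) < 0.1


def test_separable_classes_reach_high_accuracy():
    X, y = _labeled_days(sep=3.0, seed=2)
    rep = classify_days(X, y, task="event_vs_nonevent", seed=0)
    assert rep.accuracy >= 0.95
    assert rep.p_value < 0.001
    assert rep.chance == 0.5


def test_four_class_task_chance_level():
    X, y = _labeled_days(sep=2.0, seed=3)
    rep = classify_days(X, y, task="four_class", seed=0)
    assert rep.chance == 0.25
    assert rep.n_days == 4 * 60


def test_importances_sum_to_one_and_rank_informative_features():
    """A feature that fully determines the label must outrank pure noise."""
    rng = np.random.default_rng(4)
    n = 120
    y = pd.Series(["covid_event"] * (n // 2) + ["covid_nonevent"] * (n // 2))
    X = pd.DataFrame(
        {
            "sleep_duration": rng.normal(0, 1, n),  # pure noise
            "sleep_efficiency": rng.normal(0, 1, n),
            "restlessness": np.where(y == "covid_event", 5.0, -5.0),  # decisive
            "time_out": rng.normal(0, 1, n),
            "activity_level": rng.normal(0, 1, n),
        }
    )
    rep = classify_days(X, y, task="covid_vs_nocovid", seed=0)
    assert sum(rep.importances.values()) == pytest.approx(1.0)
    assert all(v >= 0 for v in rep.importances.values())
    assert rep.ranking[0] == "restlessness"
    assert rep.importances["restlessness"] > rep.importances["sleep_duration"]


def test_unbalanced_periods_subsampled_to_equality():
    X, y = _labeled_days(n_per=40, sep=1.0, seed=6)
    # drop most covid_event days to unbalance
    keep = (y != "covid_event") | (np.arange(len(y)) % 4 == 0)
    rep = classify_days(X[keep], y[keep], task="covid_vs_nocovid", seed=0)
    assert rep.n_days == 2 * 10  # balanced at the minority class size


def test_tiny_class_reduces_folds_with_warning():
    X, y = _labeled_days(n_per=3, sep=3.0, seed=7)
    with pytest.warns(UserWarning, match="folds reduced"):
        rep = classify_days(X, y, task="covid_vs_nocovid", seed=0, folds=5)
    assert rep.n_days == 6
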