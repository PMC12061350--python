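"""Participant phenotypes and day-level event separability.

Two complementary views of heterogeneity in event response:

* per-participant deltas (event-period mean minus nonevent-period mean of
  each marker) clustered with k-means, k=3 by default, to surface phenotypes
  of event impact;
* a random-forest classifier (100 trees, stratified 5-fold cross-validation)
  over the five daily markers, measuring how separable event and nonevent
  days are and ranking markers by Gini impurity importance.

The classification unit is the participant-day: the feature sets are the
daily markers.  Period class sizes are balanced by seeded subsampling before
cross-validation, so accuracy is comparable to the chance level (0.25 for
the four-class task, 0.50 for binary tasks); significance against chance is
an exact binomial test on the pooled cross-validated predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .markers import MARKER_NAMES, StudyWindow

__all__ = [
    "ParticipantDelta",
    "ClusterResult",
    "ClassifierReport",
    "participant_deltas",
    "cluster_phenotypes",
    "classify_days",
    "CLASSIFY_TASKS",
]


@dataclass
class ClusterResult:
    k: int
    assignments: dict[str, int]              # participant -> cluster id
    centroids: np.ndarray                    # k x markers, z-scored delta space
    sizes: list[int]
    # cluster -> marker -> (mean raw delta, two-sided p-value vs zero)
    cluster_stats: dict[int, dict[str, tuple[float, float]]]
    inertia: float
    markers: list[str] = field(default_factory=lambda: list(MARKER_NAMES))


@dataclass
class ClassifierReport:
    task: str
    accuracy: float
    chance: float
    p_value: float
    importances: dict[str, float]            # marker -> Gini importance
    ranking: list[str]
    n_days: int
    fold_accuracies: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------


def participant_deltas(
    markers: pd.DataFrame, window: StudyWindow, columns: list[str] | None = None
) -> pd.DataFrame:
    """Event-minus-nonevent mean of each marker, per participant.

    Rows are participants; a participant with no valid day in one of the
    periods (or an all-missing marker) is excluded with a warning.
    """
    columns = columns or list(MARKER_NAMES)
    df = markers[markers["valid"]].copy() if "valid" in markers.columns else markers.copy()
    df["period"] = df["date"].map(window.period_of)
    df = df[df["period"].notna()]
    out = {}
    for pid, grp in df.groupby("participant_id"):
        ev = grp[grp["period"] == "event"]
        ne = grp[grp["period"] == "nonevent"]
        if ev.empty or ne.empty:
            warnings.warn(
                f"participant {pid}: missing a period, excluded from deltas",
                stacklevel=2,
            )
            continue
        delta = ev[columns].mean() - ne[columns].mean()
        if delta.isna().any():
            warnings.warn(
                f"participant {pid}: missing marker mean, excluded from deltas",
                stacklevel=2,
            )
            continue
        out[str(pid)] = delta
    res = pd.DataFrame(out).T
    res.index.name = "participant_id"
    return res


# alias matching the domain-type name
ParticipantDelta = pd.Series


def cluster_phenotypes(
    deltas: pd.DataFrame, k: int = 3, seed: int = 0, n_restarts: int = 10
) -> ClusterResult:
    """K-means phenotypes on z-scored participant deltas.

    Deltas are z-scored per marker before clustering (seconds-scale markers
    would otherwise dominate the distance); per-cluster statistics are
    reported on the raw deltas, with a one-sample two-sided t-test of the
    cluster's mean delta against zero.
    """
    if len(deltas) < k:
        raise ValueError(f"need at least k={k} participants, got {len(deltas)}")
    X = deltas.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    n_distinct = np.unique(Z, axis=0).shape[0]
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct delta vectors for k={k}; "
            "fewer effective clusters",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(Z)
    stats_by_cluster: dict[int, dict[str, tuple[float, float]]] = {}
    for c in range(k):
        members = X[labels == c]
        per_marker = {}
        for j, m in enumerate(deltas.columns):
            vals = members[:, j]
            if len(vals) > 1 and np.std(vals) > 0:
                p = float(stats.ttest_1samp(vals, 0.0).pvalue)
            else:
                p = float("nan")
            per_marker[m] = (float(vals.mean()) if len(vals) else float("nan"), p)
        stats_by_cluster[c] = per_marker
    return ClusterResult(
        k=k,
        assignments={pid: int(l) for pid, l in zip(deltas.index, labels)},
        centroids=km.cluster_centers_,
        sizes=[int((labels == c).sum()) for c in range(k)],
        cluster_stats=stats_by_cluster,
        inertia=float(km.inertia_),
        markers=list(deltas.columns),
    )


# ---------------------------------------------------------------------------

CLASSIFY_TASKS = ("four_class", "event_vs_nonevent", "covid_vs_nocovid", "smoke_vs_nosmoke")


def _task_labels(labels: pd.Series, task: str) -> pd.Series | None:
    """Map (event_type, period) labels like 'covid_event' to task classes."""
    etype = labels.str.split("_").str[0]
    period = labels.str.split("_").str[1]
    if task == "four_class":
        return labels
    if task == "event_vs_nonevent":
        return period.map({"event": "positive", "nonevent": "negative"})
    if task == "covid_vs_nocovid":
        sub = labels[etype == "covid"]
        return sub
    if task == "smoke_vs_nosmoke":
        sub = labels[etype == "smoke"]
        return sub
    raise ValueError(f"unknown task {task!r}")


def _balance(idx: np.ndarray, y: pd.Series, rng: np.random.Generator) -> np.ndarray:
    counts = y.value_counts()
    n_min = int(counts.min())
    keep = []
    for cls in counts.index:
        members = idx[(y == cls).to_numpy()]
        if len(members) > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        keep.append(members)
    return np.sort(np.concatenate(keep))


def classify_days(
    markers: pd.DataFrame,
    labels: pd.Series,
    task: str = "event_vs_nonevent",
    n_trees: int = 100,
    folds: int = 5,
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> ClassifierReport:
    """Cross-validated separability of labeled participant-days.

    ``labels`` holds per-row strings ``{covid|smoke}_{event|nonevent}``
    aligned with ``markers``.  Classes are balanced by seeded subsampling;
    rows with missing features are dropped.  Accuracy is computed on pooled
    out-of-fold predictions, tested against chance with an exact binomial
    test; Gini importances are averaged over fold models and renormalized.
    """
    feature_columns = feature_columns or list(MARKER_NAMES)
    rng = np.random.default_rng(seed)
    y_task = _task_labels(labels, task)
    if y_task is None:
        raise ValueError(f"task {task!r} yielded no labels")
    y_task = y_task.dropna()
    X = markers.loc[y_task.index, feature_columns].astype(float)
    ok = X.notna().all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} day(s) with missing features", stacklevel=2)
    X, y_task = X[ok], y_task[ok]
    if y_task.nunique() < 2:
        raise ValueError("need at least two classes to classify")
    keep = _balance(np.arange(len(y_task)), y_task.reset_index(drop=True), rng)
    Xb = X.iloc[keep].to_numpy()
    yb = y_task.iloc[keep].to_numpy()

    n_classes = len(np.unique(yb))
    chance = 1.0 / n_classes
    min_class = int(pd.Series(yb).value_counts().min())
    eff_folds = min(folds, min_class)
    if eff_folds < folds:
        warnings.warn(
            f"class with only {min_class} day(s); folds reduced to {eff_folds}",
            stacklevel=2,
        )
    if eff_folds < 2:
        raise ValueError("need at least 2 days per class for cross-validation")
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    preds = np.empty(len(yb), dtype=object)
    importances = np.zeros(len(feature_columns))
    fold_acc = []
    for fold_i, (tr, te) in enumerate(skf.split(Xb, yb)):
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + fold_i
        )
        clf.fit(Xb[tr], yb[tr])
        p = clf.predict(Xb[te])
        preds[te] = p
        fold_acc.append(float(np.mean(p == yb[te])))
        importances += clf.feature_importances_
    importances /= importances.sum()
    correct = int(np.sum(preds == yb))
    accuracy = correct / len(yb)
    p_value = float(
        stats.binomtest(correct, len(yb), chance, alternative="greater").pvalue
    )
    imp = dict(zip(feature_columns, map(float, importances)))
    ranking = sorted(imp, key=imp.get, reverse=True)
    return ClassifierReport(
        task=task,
        accuracy=float(accuracy),
        chance=chance,
        p_value=p_value,
        importances=imp,
        ranking=ranking,
        n_days=int(len(yb)),
        fold_accuracies=fold_acc,
    )
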