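"""Interrupted time-series segmented regression on daily marker series.

For a marker series :math:`X_t` observed over a nonevent period followed by
an event period starting at day :math:`t_0`, the model is

.. math::

    X_t = \\beta_0 + \\beta_1 t + \\beta_2 D_t + \\beta_3 (t - t_0) D_t
          + \\gamma' z + \\varepsilon_t,

where :math:`D_t` indicates event days and :math:`z` are participant
covariates (age, gender, education).  The coefficients are the pre-event
baseline (initial level, reported at the first observed day), the pre-event
trend per day, the immediate impact on the first event day, and the
long-term trend per event day.  The counterfactual is the pre-event line
:math:`\\beta_0 + \\beta_1 t + \\gamma' \\bar z` projected past :math:`t_0`.

The default fit pools all participant-days in one OLS with
participant-clustered robust standard errors; a per-participant mode fits
each home separately and summarizes across homes.  Inference uses
:math:`\\alpha = .05` two-sided tests with no multiple-testing correction.

Reporting conventions: percent change is :math:`100\\,|\\beta_2|/|\\beta_0|`
with the direction carried separately by the sign of the impact, and
second-valued markers are converted to hours or minutes at two decimals
(one decimal for headline hour differences).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .markers import StudyWindow

__all__ = [
    "ITSFit",
    "ChangeReport",
    "fit_its",
    "fit_its_per_participant",
    "counterfactual",
    "percent_change",
    "convert_units",
    "change_report",
]

COEF_NAMES = ("initial", "pre_trend", "immediate", "long_term")
COVARIATES = ("age", "gender_male", "education")


@dataclass
class ITSFit:
    """Segmented-regression coefficient set with inference."""

    marker: str
    subgroup: str                      # total | female | male
    coef: dict[str, float]             # initial, pre_trend, immediate, long_term
    pvalues: dict[str, float]
    covariate_coef: dict[str, float]
    covariate_pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    f_stat: float
    f_df: tuple[float, float]
    f_pvalue: float
    n_days: int
    n_participants: int
    t0: int
    covariate_means: dict[str, float] = field(default_factory=dict)

    @property
    def initial(self) -> float:
        return self.coef["initial"]

    @property
    def immediate(self) -> float:
        return self.coef["immediate"]


def _design(df: pd.DataFrame, t0: int, covariates: list[str]) -> pd.DataFrame:
    t = df["t"].to_numpy(dtype=float)
    d = (t >= t0).astype(float)
    X = pd.DataFrame(
        {
            "initial": 1.0,
            "pre_trend": t,
            "immediate": d,
            "long_term": (t - t0) * d,
        },
        index=df.index,
    )
    for c in covariates:
        col = df[c].to_numpy(dtype=float)
        X[c] = col - np.nanmean(col)  # centered: intercept stays the initial level
    return X


def _attach_covariates(
    data: pd.DataFrame, covariates: pd.DataFrame | None
) -> pd.DataFrame:
    df = data.copy()
    if covariates is None:
        return df
    cov = covariates.copy()
    cov.index = cov.index.astype(str)
    df["age"] = df["participant_id"].astype(str).map(cov["age"])
    df["education"] = df["participant_id"].astype(str).map(cov["education"])
    df["gender"] = df["participant_id"].astype(str).map(cov["gender"])
    df["gender_male"] = (df["gender"] == "male").astype(float)
    return df


def fit_its(
    data: pd.DataFrame,
    marker: str,
    window: StudyWindow | None = None,
    covariates: pd.DataFrame | None = None,
    subgroup: str = "total",
    t0: int | None = None,
    cluster: bool = True,
) -> ITSFit:
    """Fit the segmented regression for one marker.

    ``data`` needs columns ``participant_id``, ``marker``, and either ``t``
    (day index) or ``date`` resolvable through ``window``.  ``covariates``
    is a frame indexed by participant_id with age/gender/education; gender
    subgroup fits drop the gender covariate (collinear).  Requires at least
    4 observed days on each side of the interruption.
    """
    df = data.copy()
    if "t" not in df.columns:
        if window is None:
            raise ValueError("need a 't' column or a StudyWindow to index days")
        idx = window.day_index()
        df = df[df["date"].isin(idx)]
        df["t"] = df["date"].map(idx)
    if t0 is None:
        if window is not None:
            t0 = window.t0
        else:
            raise ValueError("need t0 or a StudyWindow")
    df = _attach_covariates(df, covariates)
    if subgroup != "total":
        if "gender" not in df.columns:
            raise ValueError("subgroup fits require covariates with gender")
        df = df[df["gender"] == subgroup]
    df = df.dropna(subset=[marker])
    pre_days = df.loc[df["t"] < t0, "t"].nunique()
    post_days = df.loc[df["t"] >= t0, "t"].nunique()
    if pre_days < 4 or post_days < 4:
        raise ValueError(
            f"too few days for a segmented fit (pre={pre_days}, post={post_days})"
        )

    use_cov = []
    if covariates is not None:
        use_cov = [c for c in COVARIATES if c != "gender_male" or subgroup == "total"]
        kept = []
        for c in use_cov:
            col = df[c].to_numpy(dtype=float)
            if np.nanstd(col) == 0:
                warnings.warn(
                    f"covariate {c!r} is constant in this subgroup; dropped",
                    stacklevel=2,
                )
            else:
                kept.append(c)
        use_cov = kept

    X = _design(df, t0, use_cov)
    y = df[marker].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    n_participants = len(np.unique(groups))
    model = sm.OLS(y, X.to_numpy())
    if cluster and n_participants > 1:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": groups}, use_t=True
        )
    else:
        res = model.fit(use_t=True)

    names = list(X.columns)
    params = dict(zip(names, res.params))
    pvals = dict(zip(names, res.pvalues))
    ci = res.conf_int()
    cis = {n: (float(ci[i][0]), float(ci[i][1])) for i, n in enumerate(names)}
    # joint F test over the three structural terms
    R = np.zeros((3, len(names)))
    for r, nm in enumerate(("pre_trend", "immediate", "long_term")):
        R[r, names.index(nm)] = 1.0
    ftest = res.f_test(R)
    cov_means = {c: float(np.mean(df[c].to_numpy(dtype=float))) for c in use_cov}
    return ITSFit(
        marker=marker,
        subgroup=subgroup,
        coef={n: float(params[n]) for n in COEF_NAMES},
        pvalues={n: float(pvals[n]) for n in COEF_NAMES},
        covariate_coef={c: float(params[c]) for c in use_cov},
        covariate_pvalues={c: float(pvals[c]) for c in use_cov},
        conf_int={n: cis[n] for n in COEF_NAMES},
        f_stat=float(np.squeeze(ftest.fvalue)),
        f_df=(float(ftest.df_num), float(ftest.df_denom)),
        f_pvalue=float(np.squeeze(ftest.pvalue)),
        n_days=int(df["t"].nunique()),
        n_participants=n_participants,
        t0=int(t0),
        covariate_means=cov_means,
    )


def fit_its_per_participant(
    data: pd.DataFrame,
    marker: str,
    window: StudyWindow | None = None,
    t0: int | None = None,
) -> tuple[list[ITSFit], dict]:
    """Per-home fits plus an across-home summary.

    Each participant's series is fitted separately (no covariates — they are
    constant within a home).  The summary reports the mean coefficient
    vector, per-coefficient one-sample t-test p-values across homes, and a
    Hotelling T-squared F test that the three structural coefficients are
    jointly zero across homes.
    """
    fits = []
    for pid, grp in data.groupby("participant_id"):
        try:
            fits.append(
                fit_its(grp, marker, window=window, t0=t0, cluster=False)
            )
        except ValueError as err:
            warnings.warn(f"participant {pid}: {err}", stacklevel=2)
    if not fits:
        raise ValueError("no participant could be fitted")
    B = np.array([[f.coef[c] for c in COEF_NAMES] for f in fits])
    n, p3 = B.shape[0], 3
    mean = B.mean(axis=0)
    tt = {
        c: float(stats.ttest_1samp(B[:, i], 0.0).pvalue) if n > 1 else np.nan
        for i, c in enumerate(COEF_NAMES)
    }
    summary: dict = {
        "coef": dict(zip(COEF_NAMES, map(float, mean))),
        "pvalues": tt,
        "n_participants": n,
    }
    S = np.cov(B[:, 1:4], rowvar=False)
    if n > p3 and np.linalg.matrix_rank(S) == p3:
        diff = mean[1:4]
        t2 = n * diff @ np.linalg.solve(S, diff)
        fstat = (n - p3) / (p3 * (n - 1)) * t2
        df1, df2 = p3, n - p3
        summary["f_stat"] = float(fstat)
        summary["f_df"] = (df1, df2)
        summary["f_pvalue"] = float(stats.f.sf(fstat, df1, df2))
    return fits, summary


def _cov_contribution(fit: ITSFit, covariate_values: dict | None) -> float:
    # covariates enter the design centered, so the contribution at the
    # sample mean is zero and projections refer to the average participant
    if not covariate_values:
        return 0.0
    return sum(
        fit.covariate_coef[c] * (covariate_values[c] - fit.covariate_means.get(c, 0.0))
        for c in fit.covariate_coef
        if c in covariate_values
    )


def counterfactual(
    fit: ITSFit, t: int | np.ndarray, covariate_values: dict | None = None
) -> float | np.ndarray:
    """Projected marker value had the event not occurred (event terms zeroed).

    By default the projection is for the average participant; pass
    ``covariate_values`` (raw units) to project for someone else.  Only
    defined for ``t >= t0``: the pre-event period has no counterfactual.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < fit.t0):
        raise ValueError("counterfactual is only defined for t >= t0")
    out = (
        fit.coef["initial"]
        + fit.coef["pre_trend"] * t_arr
        + _cov_contribution(fit, covariate_values)
    )
    return float(out) if np.isscalar(t) else out


def fitted_line(
    fit: ITSFit, t: int | np.ndarray, covariate_values: dict | None = None
) -> float | np.ndarray:
    """The fitted event line at day ``t`` (average participant by default)."""
    t_arr = np.asarray(t, dtype=float)
    d = (t_arr >= fit.t0).astype(float)
    out = (
        fit.coef["initial"]
        + fit.coef["pre_trend"] * t_arr
        + d * (fit.coef["immediate"] + fit.coef["long_term"] * (t_arr - fit.t0))
        + _cov_contribution(fit, covariate_values)
    )
    return float(out) if np.isscalar(t) else out


def percent_change(initial: float, impact: float) -> tuple[float, str] | None:
    """Impact as a percentage of the initial level, magnitude convention.

    Returns ``(100 * |impact| / |initial|, direction)`` where direction is
    ``"decrease"`` for a negative impact, ``"increase"`` for a positive one.
    Undefined (``None``) when the initial level is zero.  Note the magnitude
    convention: markers with negative baselines on the normalized scale
    (e.g. restlessness) make signed percentages ill-defined, so the sign is
    carried separately.
    """
    if initial == 0:
        return None
    pct = 100.0 * abs(impact) / abs(initial)
    direction = "decrease" if impact < 0 else ("increase" if impact > 0 else "none")
    return pct, direction


def convert_units(seconds: float, *, decimals: int = 2) -> dict[str, float]:
    """Seconds to hours and minutes at reporting precision.

    Two decimals by default; pass ``decimals=1`` for headline hour
    differences.
    """
    return {
        "hours": round(seconds / 3600.0, decimals),
        "minutes": round(seconds / 60.0, decimals),
    }


@dataclass
class ChangeReport:
    marker: str
    initial: float
    immediate: float
    percent: float | None
    direction: str
    initial_hours: float | None = None
    event_level_hours: float | None = None
    immediate_hours_1dp: float | None = None
    immediate_minutes: float | None = None


def change_report(fit: ITSFit, seconds_scale: bool | None = None) -> ChangeReport:
    """Summarize a fit the way results are reported: percent change plus, for
    second-valued markers, hour/minute conversions of the initial level, the
    first-event-day level, and the impact."""
    if seconds_scale is None:
        seconds_scale = fit.marker in ("sleep_duration", "time_out")
    pc = percent_change(fit.initial, fit.immediate)
    pct, direction = (pc if pc is not None else (None, "undefined"))
    rep = ChangeReport(
        marker=fit.marker,
        initial=fit.initial,
        immediate=fit.immediate,
        percent=pct,
        direction=direction,
    )
    if seconds_scale:
        rep.initial_hours = convert_units(fit.initial)["hours"]
        rep.event_level_hours = convert_units(fit.initial + fit.immediate)["hours"]
        rep.immediate_hours_1dp = convert_units(abs(fit.immediate), decimals=1)["hours"]
        rep.immediate_minutes = convert_units(abs(fit.immediate))["minutes"]
    return rep
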