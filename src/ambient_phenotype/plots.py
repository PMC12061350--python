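"""Figures: radial day-rings, marker trend lines, cluster bars.

Figures are presentation artifacts; the quantities behind them (the binned
activity matrix, the per-day marker means, the cluster deltas) are exposed
as plain arrays/frames so they can be tested and exported without pixel
comparisons.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .events import SensorEvent, SensorType
from .its import ITSFit, counterfactual, fitted_line
from .phenotype import ClusterResult

__all__ = [
    "radial_activity_matrix",
    "radial_plot",
    "trend_plot",
    "cluster_bar_plot",
]

RADIAL_BIN_MIN = 15  # minutes per angular bin


def radial_activity_matrix(
    events: list[SensorEvent],
    dates: list[dt.date],
    bin_minutes: int = RADIAL_BIN_MIN,
) -> pd.DataFrame:
    """Motion-reading counts per (day, time-of-day bin).

    Rows are days, columns are ``24*60/bin_minutes`` time bins; a zero row
    renders as an all-black ring.
    """
    n_bins = (24 * 60) // bin_minutes
    mat = np.zeros((len(dates), n_bins), dtype=int)
    pos = {d: i for i, d in enumerate(dates)}
    for e in events:
        if e.sensor_type is not SensorType.MOTION:
            continue
        i = pos.get(e.timestamp.date())
        if i is None:
            continue
        minute = e.timestamp.hour * 60 + e.timestamp.minute
        mat[i, minute // bin_minutes] += 1
    return pd.DataFrame(
        mat, index=[d.isoformat() for d in dates], columns=range(n_bins)
    )


def radial_plot(
    events: list[SensorEvent],
    dates: list[dt.date],
    path: str | Path | None = None,
    bin_minutes: int = RADIAL_BIN_MIN,
    title: str | None = None,
):
    """One ring per day; angle is time of day, color is motion count
    (black = none, brighter = more)."""
    mat = radial_activity_matrix(events, dates, bin_minutes).to_numpy()
    n_days, n_bins = mat.shape
    theta = np.linspace(0, 2 * np.pi, n_bins + 1)
    r = np.arange(n_days + 1)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.pcolormesh(theta, r, mat, cmap="inferno", shading="flat")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    ax.set_xticklabels([f"{h:02d}:00" for h in range(0, 24, 3)])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def trend_plot(
    data: pd.DataFrame,
    marker: str,
    fit: ITSFit | None = None,
    path: str | Path | None = None,
):
    """Mean marker value per day index with the fitted segments and the
    counterfactual projection."""
    daily = data.groupby("t")[marker].mean()
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(daily.index, daily.to_numpy(), ".", ms=3, alpha=0.6, label="daily mean")
    if fit is not None:
        t = np.array(sorted(daily.index))
        ax.plot(t, fitted_line(fit, t), "-", color="C1", label="segmented fit")
        t_post = t[t >= fit.t0]
        if t_post.size:
            ax.plot(
                t_post, counterfactual(fit, t_post), "--", color="C2",
                label="counterfactual",
            )
        ax.axvline(fit.t0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("day index")
    ax.set_ylabel(marker)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def cluster_bar_plot(result: ClusterResult, path: str | Path | None = None):
    """Per-cluster mean marker deltas (event minus nonevent), one panel per
    cluster."""
    fig, axes = plt.subplots(1, result.k, figsize=(3.2 * result.k, 3.2), sharey=False)
    axes = np.atleast_1d(axes)
    for c, ax in enumerate(axes):
        stats = result.cluster_stats[c]
        names = list(stats)
        means = [stats[m][0] for m in names]
        ax.bar(range(len(names)), means, color="C0")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=60, ha="right", fontsize=7)
        ax.set_title(f"cluster {c} (n={result.sizes[c]})", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
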