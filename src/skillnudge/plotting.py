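"""Plots of the weekly skill-utilization series and adherence course."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd


def _ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(6, 3.5))
    return ax


def plot_weekly_series(series: pd.Series, ylabel: str, ax=None):
    """Line plot of one weekly percentage series (NaN weeks left as gaps)."""
    ax = _ax(ax)
    ax.plot(series.index, series.values, marker="o")
    ax.set_xlabel("treatment week")
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 105)
    return ax


def plot_adherence(weekly: pd.DataFrame, ax=None):
    """Entries/day by treatment week from :func:`analytics.weekly_metrics_frame`."""
    ax = _ax(ax)
    ax.plot(weekly.index, weekly["entries_per_day"], marker="o")
    ax.set_xlabel("treatment week")
    ax.set_ylabel("entries per day")
    ax.set_ylim(bottom=0)
    return ax


def plot_learning_fit(results, doses: Optional[Sequence[int]] = None, ax=None):
    """Fitted dose-response curve with binned observed skill-use rates."""
    import numpy as np

    ax = _ax(ax)
    model = results.model
    if doses is None:
        doses = np.arange(0, int(model.dose.max()) + 1)
    ax.plot(doses, results.predict(doses), label="fitted curve")
    bins = np.unique(np.quantile(model.dose, np.linspace(0, 1, 8)).astype(int))
    for lo, hi in zip(bins, list(bins[1:]) + [model.dose.max() + 1]):
        mask = (model.dose >= lo) & (model.dose < hi)
        if mask.any():
            ax.scatter((lo + hi) / 2, model.used[mask].mean(), color="k", s=18)
    ax.set_xlabel("cumulative interventions received")
    ax.set_ylabel("P(skill used)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
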