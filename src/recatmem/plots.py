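"""Basic matplotlib views of the standard summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_accuracy_by_segment(acc: pd.DataFrame, ax=None):
    """Learning curves per condition, one line per item type."""
    if ax is None:
        _, ax = plt.subplots()
    for (condition, item_type), grp in acc.groupby(["condition", "item_type"]):
        grp = grp.sort_values("segment")
        ax.errorbar(
            grp["segment"], grp["accuracy"], yerr=grp["sem"],
            label=f"{condition} / {item_type}", capsize=2,
        )
    ax.set_xlabel("segment")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax


def plot_fit_curves(curves: pd.DataFrame, condition: str, ax=None):
    """Mean fit statistic per segment, one line per model family."""
    if ax is None:
        _, ax = plt.subplots()
    sub = curves[curves["condition"] == condition]
    for family, grp in sub.groupby("family"):
        grp = grp.sort_values("segment")
        ax.errorbar(
            grp["segment"], grp["mean"], yerr=grp["sem"], label=family, capsize=2
        )
    ax.set_xlabel("segment")
    ax.set_ylabel("fit statistic")
    ax.set_title(condition)
    ax.legend(fontsize=8)
    return ax


def plot_need_odds(profile, ax=None):
    """Need odds against recency (log-log), the environment's signature."""
    if ax is None:
        _, ax = plt.subplots()
    df = profile.need_odds
    ax.plot(df["recency"], df["need_odds"], marker="o", ms=3)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("recency (trials)")
    ax.set_ylabel("need odds P/(1-P)")
    return ax
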