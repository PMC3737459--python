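"""Small plotting helpers (values faithful, aesthetics minimal)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .contributions import NULL_THRESHOLD


def plot_va_grid(features: pd.DataFrame, predictions: dict[str, list[float]] | None = None):
    """Scatter the excerpts on the valence-arousal plane; optionally overlay
    model predictions (excerpt -> [valence, arousal])."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(features["mean_valence"], features["mean_arousal"], label="ratings")
    for e, row in features.iterrows():
        ax.annotate(str(e), (row["mean_valence"], row["mean_arousal"]), fontsize=8)
    if predictions:
        pv = [v[0] for v in predictions.values()]
        pa = [v[1] for v in predictions.values()]
        ax.scatter(pv, pa, marker="x", label="model")
    ax.axhline(5, color="grey", lw=0.5)
    ax.axvline(5, color="grey", lw=0.5)
    ax.set(xlim=(1, 9), ylim=(1, 9), xlabel="valence", ylabel="arousal")
    ax.legend()
    return fig


def plot_contributions(mean_contrib: pd.DataFrame):
    """Bar chart of trial-mean signed contributions per output, with the
    +/- null-threshold band."""
    outputs = list(mean_contrib.columns)
    fig, axes = plt.subplots(1, len(outputs), figsize=(4 * len(outputs), 3.5), sharey=True)
    axes = [axes] if len(outputs) == 1 else list(axes)
    for ax, o in zip(axes, outputs):
        ax.bar(mean_contrib.index, mean_contrib[o])
        for s in (+1, -1):
            ax.axhline(s * NULL_THRESHOLD, color="red", ls="--", lw=0.8)
        ax.axhline(0, color="black", lw=0.8)
        ax.set_title(o)
    fig.tight_layout()
    return fig
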