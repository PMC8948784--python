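"""Plot helpers: spectrum heat maps with discriminatory-feature overlays, ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import pandas as pd

from .io import GCIMSSpectrum

__all__ = ["plot_spectrum", "plot_roc"]


def plot_spectrum(spectrum: GCIMSSpectrum, markers: pd.DataFrame | None = None, ax=None):
    """Heat map of a GC-IMS spectrum (retention on y, drift on x).

    ``markers`` is the overlay table from
    :func:`voccast.preprocess.replot_features`; each selected feature is drawn
    as a bullet at its (drift, retention) coordinate.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.pcolormesh(
        spectrum.drift_axis,
        spectrum.retention_axis,
        spectrum.intensities,
        shading="nearest",
        cmap="viridis",
    )
    if markers is not None and len(markers):
        ax.scatter(
            markers["drift_time"],
            markers["retention_time"],
            s=14,
            facecolors="none",
            edgecolors="red",
            linewidths=0.8,
        )
    ax.set_xlabel("drift time")
    ax.set_ylabel("retention time")
    ax.set_title(spectrum.sample_id)
    return ax


def plot_roc(points: pd.DataFrame, auc: float | None = None, label: str = "", ax=None):
    """ROC curve from the (fpr, tpr) table produced by :func:`voccast.evaluate.roc_points`."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    legend = f"{label} (AUC {auc:.2f})" if auc is not None else label
    ax.plot(points["fpr"], points["tpr"], label=legend)
    ax.plot([0, 1], [0, 1], "k:", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if legend:
        ax.legend(loc="lower right")
    return ax
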