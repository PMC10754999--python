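"""Figures: mean spectra with envelopes, one-vs-rest ROC overlays, metric bars.

The wavenumber axis is drawn descending left-to-right (spectroscopy
convention); data files always store ascending axes.  All functions accept
an optional matplotlib Axes and return the Axes they drew on.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .spectra import SpectralDataset, mean_spectrum_by_class


def plot_mean_spectra(ds: SpectralDataset, ax=None, descending: bool = True):
    """Per-class mean spectra (lines) with pointwise min-max envelopes (shaded)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    wn = ds.grid.wavenumbers
    summary = mean_spectrum_by_class(ds)
    for cname in ds.class_names:
        s = summary[cname]
        (line,) = ax.plot(wn, s["mean"], label=cname, lw=1.2)
        ax.fill_between(wn, s["lower"], s["upper"], color=line.get_color(), alpha=0.2, lw=0)
    ax.set_xlabel("Wavenumber (cm$^{-1}$)")
    ax.set_ylabel("Absorbance (a.u.)")
    ax.set_xlim(wn[0], wn[-1])
    if descending:
        ax.invert_xaxis()
    ax.legend()
    return ax


def plot_roc(report_or_curves, ax=None, label_prefix: str = ""):
    """One-vs-rest ROC curves with per-class AUC in the legend.

    Accepts a :class:`~ftirnet.metrics.MetricsReport` (uses its curves and
    per-class AUCs) or a dict ``{class: {"fpr": ..., "tpr": ...}}``.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if hasattr(report_or_curves, "roc_curves"):
        curves = report_or_curves.roc_curves
        aucs = report_or_curves.per_class_auc
    else:
        curves, aucs = report_or_curves, {}
    for cname, c in curves.items():
        lab = f"{label_prefix}{cname}"
        if cname in aucs:
            lab += f" (AUC {aucs[cname]:.3f})"
        ax.plot(c["fpr"], c["tpr"], lw=1.2, label=lab)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_metric_bars(scalars_by_model: dict, ax=None):
    """Grouped bars of accuracy/sensitivity/precision/specificity per model."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    metrics = ["accuracy", "sensitivity", "precision", "specificity"]
    models = list(scalars_by_model)
    width = 0.8 / max(len(models), 1)
    x = np.arange(len(metrics))
    for i, m in enumerate(models):
        vals = [scalars_by_model[m].get(k, np.nan) for k in metrics]
        ax.bar(x + i * width, vals, width=width, label=m)
    ax.set_xticks(x + width * (len(models) - 1) / 2)
    ax.set_xticklabels(metrics)
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("Value")
    ax.legend(fontsize=8)
    return ax
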