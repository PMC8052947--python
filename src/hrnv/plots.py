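"""Figure emitters: threshold sweep, dimension sweep, ROC and calibration plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_threshold_sweep(curve: pd.DataFrame, path: str | Path) -> None:
    """AUC vs threshold and retained-variable count vs threshold (two panels)."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    c = curve.sort_values("threshold")
    ax1.semilogx(c["threshold"], c["cv_auc"], "o-")
    ax1.set_xlabel("p-value threshold")
    ax1.set_ylabel("5-fold CV AUC")
    ax2.semilogx(c["threshold"], c["n_retained"], "s-")
    ax2.set_xlabel("p-value threshold")
    ax2.set_ylabel("variables retained")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dimension_sweep(sweeps: pd.DataFrame, path: str | Path) -> None:
    """AUC vs target dimension, one curve per reduction method."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in sweeps.groupby("method"):
        g = grp.sort_values("d")
        ax.plot(g["d"], g["auc"], "o-", label=method)
    ax.set_xlabel("feature dimension d")
    ax.set_ylabel("5-fold CV AUC")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(reports, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for r in reports:
        ax.plot(r.roc["fpr"], r.roc["tpr"], lw=1,
                label=f"{r.name} ({r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_calibration(reports, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for r in reports:
        ax.plot(r.calibration["mean_predicted"],
                r.calibration["observed_fraction"], "o-", lw=1, label=r.name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
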