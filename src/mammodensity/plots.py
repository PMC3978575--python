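"""Optional diagnostic plots for the analysis reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .validation_stats import AgreementReport

__all__ = ["plot_roc", "plot_bland_altman"]


def plot_roc(curves: dict[str, pd.DataFrame], path: str | Path) -> None:
    """ROC curves (one per labelled contrast) on a single panel."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(curve["fpr"], curve["tpr"], label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_bland_altman(
    measure_a, measure_b, report: AgreementReport, path: str | Path
) -> None:
    """Bland-Altman plot of log dense areas with limits of agreement."""
    a = np.log(np.asarray(measure_a, dtype=float))
    b = np.log(np.asarray(measure_b, dtype=float))
    mean = (a + b) / 2.0
    diff = a - b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=4, alpha=0.4)
    for y, style in (
        (report.ba_mean_diff, "-"),
        (report.ba_lo, "--"),
        (report.ba_hi, "--"),
    ):
        ax.axhline(y, color="red", linestyle=style, lw=0.8)
    ax.set_xlabel("Mean of log dense areas")
    ax.set_ylabel("Difference of log dense areas")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
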