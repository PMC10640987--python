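"""Figure output: group mean spectra, difference spectra, ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .evaluate import ROCCurve, difference_spectra, group_spectra
from .spectrum import CLASS_LABELS

_COLORS = {"cancer": "tab:red", "benign": "tab:orange", "normal": "tab:green"}


def plot_group_spectra(
    features: np.ndarray, labels: np.ndarray, wavenumbers: np.ndarray, path: str | Path
) -> None:
    """Per-class mean spectrum with a +/- 1 SD band."""
    groups = group_spectra(features, labels)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for cls in CLASS_LABELS:
        mean, sd = groups[cls]
        ax.plot(wavenumbers, mean, color=_COLORS[cls], label=cls, lw=1.0)
        ax.fill_between(wavenumbers, mean - sd, mean + sd, color=_COLORS[cls], alpha=0.2)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_difference_spectra(
    features: np.ndarray, labels: np.ndarray, wavenumbers: np.ndarray, path: str | Path
) -> None:
    diffs = difference_spectra(features, labels)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for (a, b), curve in diffs.items():
        ax.plot(wavenumbers, curve, label=f"{a} $-$ {b}", lw=1.0)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("$\\Delta$ normalized intensity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc_curves(curves: dict[str, ROCCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, color=_COLORS[cls],
                label=f"{cls} (AUC = {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = ["plot_group_spectra", "plot_difference_spectra", "plot_roc_curves"]
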