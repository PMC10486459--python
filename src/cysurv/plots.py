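"""Optional figure helpers: ROC curves per combination and KM curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import KMResult, ROCResult

__all__ = ["plot_roc", "plot_km"]


def plot_roc(results: dict[str, ROCResult], path: str | Path | None = None):
    """Overlay ROC curves, one per descriptor combination."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in results.items():
        ax.plot(r.fpr, r.tpr, label=f"{name} (AUC {r.auc:.2f} ± {r.se:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_km(result: KMResult, path: str | Path | None = None):
    """Step plot of the per-group Kaplan-Meier survival curves."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for name, curve in result.curves.items():
        times = [0.0, *curve.time.tolist()]
        surv = [1.0, *curve.survival.tolist()]
        ax.step(times, surv, where="post",
                label=f"{name} (n={result.group_sizes.get(name, '?')})")
    label = "log-rank p undefined" if result.degenerate else (
        f"log-rank p = {result.p_value:.2g}")
    ax.set_title(label, fontsize=9)
    ax.set_xlabel("Months since cystectomy")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
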