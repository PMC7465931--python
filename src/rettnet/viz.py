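"""Figure rendering: architecture heat-maps and confusion matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .network import ArchitectureMatrix  # noqa: E402
from .predict import PredictionReport  # noqa: E402


def plot_architecture(arch: ArchitectureMatrix, path: str | Path,
                      cmap: str = "viridis") -> Path:
    """Heat-map of a coherence-feature covariance matrix."""
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(arch.matrix, cmap=cmap)
    ticks = np.arange(len(arch.feature_names))
    ax.set_xticks(ticks, arch.feature_names, rotation=90, fontsize=5)
    ax.set_yticks(ticks, arch.feature_names, fontsize=5)
    cell = ", ".join(f"{k}={v}" for k, v in arch.cell.items())
    ax.set_title(f"Network architecture ({arch.kind})\n{cell} "
                 f"(n={arch.n_rows})")
    fig.colorbar(im, ax=ax, label=arch.kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_confusion(report: PredictionReport, path: str | Path) -> Path:
    """2x2 pooled confusion matrix with counts."""
    cm = report.confusion_matrix
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(cm, cmap="Blues", vmin=0)
    for (r, c), v in np.ndenumerate(cm):
        ax.text(c, r, str(v), ha="center", va="center", fontsize=16)
    ax.set_xticks([0, 1], ["responder", "nonresponder"])
    ax.set_yticks([0, 1], ["responder", "nonresponder"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"accuracy {report.accuracy:.2f} "
                 f"(sens {report.sensitivity:.2f}, "
                 f"spec {report.specificity:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
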