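"""Generic plotting helpers: similarity heatmaps and trajectory series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .representation import SimilarityMatrix
from .trajectory import TrajectoryRecord


def plot_matrix(matrix: SimilarityMatrix, path: str, title: str = "") -> None:
    """Heatmap of a similarity matrix in its stored category order."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_title(title or matrix.kind)
    if len(matrix.names) <= 30:
        ax.set_xticks(range(len(matrix.names)), matrix.names,
                      rotation=90, fontsize=6)
        ax.set_yticks(range(len(matrix.names)), matrix.names, fontsize=6)
    fig.colorbar(im, ax=ax, label="similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory(record: TrajectoryRecord, path: str) -> None:
    """Global/coarse/fine correspondence (and performance) per stage."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = record.stage_index
    ax.plot(x, record.r_global, marker="o", label="global")
    ax.plot(x, record.r_coarse, marker="s", label="coarse")
    ax.plot(x, record.r_fine_mean, marker="^", label="fine (mean)")
    ax.set_xlabel("training stage")
    ax.set_ylabel("correspondence r")
    if record.performance is not None:
        ax2 = ax.twinx()
        ax2.plot(x, record.performance, color="gray", linestyle="--",
                 label="performance")
        ax2.set_ylabel("task performance")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
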