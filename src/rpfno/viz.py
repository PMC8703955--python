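"""Plot helpers: cross-subject MSE heat maps and learning curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_mse_matrix(report, path) -> None:
    """Heat map of the S x S cross-subject MSE matrix."""
    matrix = np.asarray(report.mse_matrix)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, cmap="viridis")
    ax.set_xticks(range(len(report.subject_ids)), report.subject_ids)
    ax.set_yticks(range(len(report.subject_ids)), report.subject_ids)
    ax.set_xlabel("test subject")
    ax.set_ylabel("model subject")
    ax.set_title(f"{report.model_kind.upper()} cross-subject MSE")
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            ax.text(j, i, f"{matrix[i, j]:.3f}", ha="center", va="center",
                    color="w", fontsize=7)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_learning_curves(curves, path, title: str = "learning curves") -> None:
    """Training/validation loss per epoch."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curves.train, label="train")
    if curves.validation and np.isfinite(curves.validation).any():
        ax.plot(curves.validation, label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MSE")
    ax.set_yscale("log")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
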