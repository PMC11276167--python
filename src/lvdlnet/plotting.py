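"""Plot helpers: training history, confusion matrices, t-SNE maps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_history(history, path) -> None:
    """Training loss and validation accuracy over epochs."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(history["epoch"], history["train_loss"], color="tab:blue", label="train loss")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("train loss", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(history["epoch"], history["val_acc"], color="tab:orange", label="val acc")
    ax2.set_ylabel("validation accuracy", color="tab:orange")
    ax2.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_confusion(cm: np.ndarray, path, class_labels=None) -> None:
    """Heatmap of a confusion matrix with counts annotated."""
    cm = np.asarray(cm)
    k = cm.shape[0]
    labels = class_labels or [f"{20 * i}%" for i in range(k)]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(k):
        for j in range(k):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    color="white" if cm[i, j] > cm.max() / 2 else "black")
    ax.set_xticks(range(k), labels, rotation=45)
    ax.set_yticks(range(k), labels)
    ax.set_xlabel("predicted level")
    ax.set_ylabel("true level")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_embedding(coords: np.ndarray, labels: np.ndarray, path) -> None:
    """Scatter of a 2-D embedding colored by adulteration level."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=labels, cmap="viridis", s=12)
    fig.colorbar(sc, ax=ax, label="class")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
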