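"""Track-strip plots: predicted vs. true label per frame over time."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap
from matplotlib.patches import Patch

from .frames import CLASSES, as_label_indices

# one distinct color per tissue class, stomach-red to squamous-pale
CLASS_COLORS = ["#8c2d04", "#d94801", "#fd8d3c", "#fdbe85", "#feedde"]
_CMAP = ListedColormap(CLASS_COLORS)


def plot_label_tracks(tracks: Mapping[str, Sequence], path: str | Path,
                      title: str | None = None) -> Path:
    """Horizontal label strips, one row per named track.

    ``tracks`` maps a row name (e.g. "truth", "fc", "lstm") to a label
    sequence; all strips share the time axis, so prediction instability is
    visible as color flicker against the smooth ground-truth strip.
    """
    names = list(tracks)
    if not names:
        raise ValueError("no tracks to plot")
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 0.6 * len(names) + 1.2),
                             squeeze=False, sharex=True)
    for ax, name in zip(axes[:, 0], names):
        labels = as_label_indices(tracks[name])
        ax.imshow(labels[None, :], aspect="auto", cmap=_CMAP, vmin=0,
                  vmax=len(CLASSES) - 1, interpolation="nearest")
        ax.set_yticks([])
        ax.set_ylabel(name, rotation=0, ha="right", va="center", fontsize=9)
    axes[-1, 0].set_xlabel("frame")
    handles = [Patch(color=c, label=l) for c, l in zip(CLASS_COLORS, CLASSES)]
    fig.legend(handles=handles, loc="upper right", ncol=len(CLASSES), fontsize=8)
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout(rect=(0, 0, 1, 0.92))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_confusion(confusion_percent: np.ndarray, path: str | Path,
                   title: str | None = None) -> Path:
    """Heatmap of a patient-normalized percentage confusion matrix."""
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    M = np.asarray(confusion_percent, dtype=float)
    im = ax.imshow(M, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(len(CLASSES)), CLASSES)
    ax.set_yticks(range(len(CLASSES)), CLASSES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(CLASSES)):
        for j in range(len(CLASSES)):
            if np.isfinite(M[i, j]):
                ax.text(j, i, f"{M[i, j]:.0f}", ha="center", va="center",
                        fontsize=8, color="black" if M[i, j] < 60 else "white")
    fig.colorbar(im, ax=ax, label="%")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
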