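"""Core containers for pullback-video frame data.

A pullback video records the withdrawal of an endoscope from the stomach up
to healthy squamous esophagus in one smooth movement, so tissue classes
appear in a fixed anatomical order:

    stomach (St) -> transition Z-line (Tz) -> Barrett (B)
                 -> transition squamous (Ts) -> squamous (Sq)

Frames are stored as float arrays with intensities in [0, 1]; labels are
stored internally as integer indices into :data:`CLASSES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: The five tissue classes in anatomical pullback order.
CLASSES: tuple[str, ...] = ("St", "Tz", "B", "Ts", "Sq")

CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

N_CLASSES = len(CLASSES)


def as_label_indices(labels: Sequence[str] | Sequence[int] | np.ndarray) -> np.ndarray:
    """Normalize a label sequence (names or indices) to an int array.

    Raises ``ValueError`` on any label outside the five-class alphabet.
    """
    arr = np.asarray(labels)
    if arr.size == 0:
        return arr.astype(np.int64).reshape(-1)
    if arr.dtype.kind in "iu":
        out = arr.astype(np.int64)
        if out.min() < 0 or out.max() >= N_CLASSES:
            raise ValueError(f"label index out of range 0..{N_CLASSES - 1}")
        return out
    out = np.empty(arr.shape, dtype=np.int64)
    flat_in, flat_out = arr.reshape(-1), out.reshape(-1)
    for i, name in enumerate(flat_in):
        try:
            flat_out[i] = CLASS_TO_INDEX[str(name)]
        except KeyError:
            raise ValueError(f"unknown tissue label {name!r} (row {i})") from None
    return out


def label_names(indices: np.ndarray) -> list[str]:
    return [CLASSES[i] for i in np.asarray(indices).reshape(-1)]


@dataclass
class Frame:
    """One time-stamped endoscopic frame with its annotation."""

    image: np.ndarray  # (H, W, 3), float, intensities in [0, 1]
    label: str
    informative: bool
    patient_id: str
    video_id: str
    frame_index: int

    def validate(self) -> None:
        if self.label not in CLASS_TO_INDEX:
            raise ValueError(f"unknown tissue label {self.label!r}")
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"image must be (H, W, 3), got {img.shape}")
        if not np.all(np.isfinite(img)):
            raise ValueError("image contains non-finite values")
        if img.min() < 0.0 or img.max() > 1.0:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")


@dataclass
class PullbackVideo:
    """Ordered frames of one pullback procedure.

    Stored columnar for efficiency: ``images`` is (T, H, W, 3); ``labels``
    holds class indices into :data:`CLASSES`.  The label sequence of a valid
    pullback visits the classes in anatomical order, each as one contiguous
    run.  This is the unit over which prediction stability is measured.
    """

    patient_id: str
    video_id: str
    images: np.ndarray
    labels: np.ndarray
    informative: np.ndarray
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = as_label_indices(self.labels)
        self.informative = np.asarray(self.informative, dtype=bool)
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.labels))
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.images.shape[0])

    def __iter__(self) -> Iterator[Frame]:
        for t in range(len(self)):
            yield self.frame(t)

    def frame(self, t: int) -> Frame:
        return Frame(
            image=self.images[t],
            label=CLASSES[self.labels[t]],
            informative=bool(self.informative[t]),
            patient_id=self.patient_id,
            video_id=self.video_id,
            frame_index=int(self.frame_index[t]),
        )

    @property
    def label_names(self) -> list[str]:
        return label_names(self.labels)

    def validate(self) -> None:
        T = len(self)
        if not (self.labels.shape == self.informative.shape == self.frame_index.shape == (T,)):
            raise ValueError("images, labels, informative and frame_index must agree in length")
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("images contain non-finite values")
        if self.images.min() < 0.0 or self.images.max() > 1.0:
            raise ValueError("image intensities must lie in [0, 1]")
        # one contiguous run per class, in anatomical order (strictly
        # increasing run labels forbid both revisits and out-of-order runs)
        runs = run_labels(self.labels)
        if runs.size and np.any(np.diff(runs) <= 0):
            raise ValueError("label runs must follow the anatomical order St→Tz→B→Ts→Sq")


def run_labels(labels: np.ndarray) -> np.ndarray:
    """Deduplicate consecutive repeats: the label of each maximal run."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return labels
    keep = np.r_[True, labels[1:] != labels[:-1]]
    return labels[keep]


@dataclass
class ClassProbTrack:
    """Per-frame class-probability rows aligned to frame_index."""

    probs: np.ndarray  # (T, 5), each row on the simplex
    frame_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_CLASSES:
            raise ValueError(f"probs must be (T, {N_CLASSES}), got {self.probs.shape}")
        if self.frame_index is None:
            self.frame_index = np.arange(self.probs.shape[0])
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.probs.shape[0])

    def validate(self, atol: float = 1e-6) -> None:
        if np.any(self.probs < -atol):
            raise ValueError("probability rows must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=atol):
            raise ValueError("probability rows must sum to 1")


@dataclass
class LabelTrack:
    """Per-frame hard labels aligned to frame_index."""

    labels: np.ndarray  # (T,) class indices
    frame_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = as_label_indices(self.labels)
        if self.frame_index is None:
            self.frame_index = np.arange(self.labels.shape[0])
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    @property
    def names(self) -> list[str]:
        return label_names(self.labels)
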