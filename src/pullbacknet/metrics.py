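"""Evaluation metrics for temporal tissue classification.

Two bespoke measures are implemented:

*Correspondence-mapped label accuracy.*  Transition zones have no hard
visual border, so a prediction is counted as a true positive when the
ground-truth label lies in a set of acceptable labels for that prediction
(the correspondence map).  Per-video accuracy is the mean true-positive
indicator over frames,

    LabelAcc(L) = (1/Nv) * sum_j TP_j ,

and the headline score averages per-patient accuracies (unweighted, which
normalizes for variable video length),

    MeanLabelAccuracy = (1/Np) * sum_i Acc(L_i) .

*Label-switch stability.*  The number of times the predicted label changes
between consecutive frames of one video.  A pullback traverses the five
classes once each, so a perfect prediction track switches exactly 4 times.

Accuracy is evaluated over informative frames only (only those carry
trusted annotations); stability is counted over the full prediction track,
since a live system must emit a label for every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .frames import CLASSES, N_CLASSES, LabelTrack, as_label_indices

_DEFAULT_MAP: dict[str, tuple[str, ...]] = {
    "St": ("St",),
    "Tz": ("Tz", "B"),
    "B": ("Tz", "B", "Ts"),
    "Ts": ("B", "Ts"),
    "Sq": ("Sq",),
}


class CorrespondenceMap:
    """Predicted label -> set of ground-truth labels counted as correct.

    The default map absorbs transition-zone ambiguity: a predicted
    transition label is accepted when the truth is the transition itself or
    its adjacent distinct class, and predicted Barrett accepts either
    transition zone.  Every predicted label must accept itself.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None):
        mapping = _DEFAULT_MAP if mapping is None else mapping
        matrix = np.zeros((N_CLASSES, N_CLASSES), dtype=bool)
        for pred, accepted in mapping.items():
            p = _single_index(pred)
            if len(accepted) == 0:
                raise ValueError(f"accepted set for {pred!r} is empty")
            for a in accepted:
                matrix[p, _single_index(a)] = True
        for p in range(N_CLASSES):
            if not matrix[p, p]:
                raise ValueError(f"map for {CLASSES[p]!r} must accept itself")
        self.matrix = matrix  # [predicted, truth]

    @classmethod
    def identity(cls) -> "CorrespondenceMap":
        """Each label accepts only itself: plain frame accuracy."""
        return cls({c: (c,) for c in CLASSES})

    def accepts(self, predicted_idx: np.ndarray, truth_idx: np.ndarray) -> np.ndarray:
        return self.matrix[predicted_idx, truth_idx]


def _single_index(label) -> int:
    return int(as_label_indices([label])[0])


def is_true_positive(predicted, truth, cmap: CorrespondenceMap | None = None) -> bool:
    """Whether a prediction counts as correct under the correspondence map."""
    cmap = cmap or CorrespondenceMap()
    return bool(cmap.matrix[_single_index(predicted), _single_index(truth)])


def _track_indices(track) -> np.ndarray:
    if isinstance(track, LabelTrack):
        return track.labels
    return as_label_indices(track)


def label_accuracy(pred, truth, cmap: CorrespondenceMap | None = None,
                   mask: np.ndarray | None = None) -> float:
    """Fraction of frames whose prediction is a correspondence-mapped TP.

    ``mask`` restricts scoring to selected frames (typically the
    informative ones); with the identity map this reduces to plain frame
    accuracy.
    """
    cmap = cmap or CorrespondenceMap()
    p, t = _track_indices(pred), _track_indices(truth)
    if p.shape != t.shape:
        raise ValueError(f"track lengths differ: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("cannot score an empty track")
    tp = cmap.accepts(p, t)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != p.shape:
            raise ValueError("mask length must match track length")
        if not mask.any():
            raise ValueError("mask selects no frames")
        tp = tp[mask]
    return float(tp.mean())


def mean_label_accuracy(per_patient: Sequence[float]) -> float:
    """Unweighted mean of per-patient accuracies (video-length invariant)."""
    accs = np.asarray(list(per_patient), dtype=float)
    if accs.size == 0:
        raise ValueError("need at least one patient accuracy")
    return float(accs.mean())


def count_label_switches(track) -> int:
    """Number of adjacent frame pairs with differing predicted labels.

    Equals (number of maximal constant runs) - 1; an ideal pullback
    prediction visits each class once and scores exactly 4.
    """
    labels = _track_indices(track)
    if labels.size == 0:
        raise ValueError("cannot count switches of an empty track")
    return int(np.count_nonzero(labels[1:] != labels[:-1]))


def per_class_accuracy(pred, truth, cmap: CorrespondenceMap | None = None,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Mapped accuracy restricted to frames of each true class (NaN if absent)."""
    cmap = cmap or CorrespondenceMap()
    p, t = _track_indices(pred), _track_indices(truth)
    tp = cmap.accepts(p, t)
    keep = np.ones_like(tp, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    out = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        sel = keep & (t == c)
        if sel.any():
            out[c] = tp[sel].mean()
    return out


def confusion_matrix(per_patient_tracks: Sequence[tuple]) -> np.ndarray:
    """Patient-normalized confusion matrix, in percent.

    ``per_patient_tracks`` holds one ``(pred, truth)`` pair of tracks per
    patient (raw labels, no correspondence mapping).  Each patient's count
    matrix is row-normalized (rows = true label, columns = predicted), then
    rows are averaged over the patients that possess that true class, and
    scaled to percent.  Rows with data sum to 100; a true class seen by no
    patient yields a NaN row.
    """
    if len(per_patient_tracks) == 0:
        raise ValueError("need at least one patient")
    row_sum = np.zeros((N_CLASSES, N_CLASSES))
    row_n = np.zeros(N_CLASSES)
    for pred, truth in per_patient_tracks:
        p, t = _track_indices(pred), _track_indices(truth)
        counts = np.zeros((N_CLASSES, N_CLASSES))
        np.add.at(counts, (t, p), 1.0)
        totals = counts.sum(axis=1)
        for c in np.nonzero(totals)[0]:
            row_sum[c] += counts[c] / totals[c]
            row_n[c] += 1
    out = np.full((N_CLASSES, N_CLASSES), np.nan)
    present = row_n > 0
    out[present] = 100.0 * row_sum[present] / row_n[present, None]
    return out


@dataclass
class EvaluationResult:
    """Per-patient and per-video evaluation quantities for one model.

    ``per_patient_accuracy`` holds Acc(L_i) per patient (frames of all of a
    patient's videos pooled); ``per_video_switches`` the stability counts;
    ``confusion`` the patient-normalized percentage matrix.
    """

    patient_ids: list[str]
    per_patient_accuracy: np.ndarray
    video_ids: list[str]
    per_video_switches: np.ndarray
    per_class_accuracy: np.ndarray
    confusion: np.ndarray
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_patient_accuracy = np.asarray(self.per_patient_accuracy, dtype=float)
        self.per_video_switches = np.asarray(self.per_video_switches)
        if np.any(self.per_patient_accuracy < 0) or np.any(self.per_patient_accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        if np.any(self.per_video_switches < 0):
            raise ValueError("switch counts must be >= 0")
        self.mean_accuracy = mean_label_accuracy(self.per_patient_accuracy)

    @property
    def mean_switches(self) -> float:
        return float(self.per_video_switches.mean())

    @property
    def sd_switches(self) -> float:
        return float(self.per_video_switches.std(ddof=1)) if len(self.per_video_switches) > 1 else 0.0
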