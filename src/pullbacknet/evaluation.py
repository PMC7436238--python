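"""Patient-level cross-validation and the four-head comparison experiment.

Folds are assigned at the patient level so no patient contributes frames to
both the training and test side of any fold; the several videos of one
patient always travel together.  Per-patient accuracies pool all of a
patient's test frames; stability is scored per video.  Head comparisons use
the Wilcoxon signed-rank test on matched per-patient accuracies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .frames import CLASSES, LabelTrack, PullbackVideo
from .metrics import (
    CorrespondenceMap,
    confusion_matrix,
    count_label_switches,
    label_accuracy,
    mean_label_accuracy,
    per_class_accuracy,
)
from .models import HEAD_KINDS, ModelSpec, TissueClassifier, causal_average, decode_labels
from .training import TrainConfig, train


def make_folds(patient_ids: Sequence[str], k: int, seed: int) -> dict[str, int]:
    """Seeded random partition of patients into k folds of near-equal size."""
    patients = sorted(set(patient_ids))
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(patients):
        raise ValueError(f"cannot make {k} folds from {len(patients)} patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    return {patients[idx]: int(i % k) for i, idx in enumerate(order)}


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    degenerate: bool = False


def wilcoxon_signed_rank(paired: Sequence[tuple[float, float]]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on matched pairs.

    Zero differences are dropped; tied ranks are mid-ranked.  The exact
    null distribution is used for up to 25 non-zero differences, the normal
    approximation with continuity correction above that.  If every pair is
    tied the result is flagged degenerate (p = 1 by convention).
    """
    arr = np.asarray(list(paired), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("paired must be a sequence of (a, b) tuples")
    diffs = arr[:, 0] - arr[:, 1]
    nz = int(np.count_nonzero(diffs))
    if nz == 0:
        return WilcoxonResult(statistic=float("nan"), p_value=1.0, n_nonzero=0,
                              degenerate=True)
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(arr[:, 0], arr[:, 1], zero_method="wilcox",
                         correction=(method == "approx"), alternative="two-sided",
                         method=method)
    return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n_nonzero=nz)


def predict_track(model: TissueClassifier, video: PullbackVideo, head_kind: str,
                  avg_window: int = 5) -> LabelTrack:
    """Decoded prediction track of one head variant for one video.

    ``fc_avg`` reuses an FC model's probabilities and applies the causal
    averaging filter — exactly how the averaged classifier is defined.
    """
    track = model.predict_video(video)
    if head_kind == "fc_avg" and model.spec.head_kind == "fc":
        track = causal_average(track, avg_window)
    return decode_labels(track)


@dataclass
class HeadSummary:
    """Cross-validated scores of one classifier head."""

    head_kind: str
    patient_ids: list[str]
    per_patient_accuracy: np.ndarray
    per_video_switches: np.ndarray
    per_class_accuracy: np.ndarray  # (5,), NaN when a class was never seen
    confusion: np.ndarray  # (5, 5) percent
    mean_accuracy: float = field(init=False)
    mean_switches: float = field(init=False)
    sd_switches: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_patient_accuracy = np.asarray(self.per_patient_accuracy, dtype=float)
        self.per_video_switches = np.asarray(self.per_video_switches, dtype=float)
        self.mean_accuracy = mean_label_accuracy(self.per_patient_accuracy)
        self.mean_switches = float(self.per_video_switches.mean())
        self.sd_switches = (float(self.per_video_switches.std(ddof=1))
                            if self.per_video_switches.size > 1 else 0.0)


@dataclass
class ExperimentReport:
    """Summary of the head-comparison experiment (accuracy table layout +
    stability + pairwise Wilcoxon p-values on per-patient accuracies)."""

    heads: dict[str, HeadSummary]
    pairwise_p: dict[str, WilcoxonResult]
    k: int
    seed: int
    # video_id -> {"truth": labels, <head_kind>: predicted labels}; filled
    # when run_cross_validation(collect_tracks=True), for track-strip plots
    tracks: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def accuracy_table(self) -> pd.DataFrame:
        """Per-class and overall mean accuracies in percent, one column per head."""
        cols = {}
        for kind, s in self.heads.items():
            cols[kind] = list(100.0 * s.per_class_accuracy) + [100.0 * s.mean_accuracy]
        return pd.DataFrame(cols, index=list(CLASSES) + ["Overall"])

    def switch_table(self) -> pd.DataFrame:
        rows = {k: {"mean_switches": s.mean_switches, "sd_switches": s.sd_switches}
                for k, s in self.heads.items()}
        return pd.DataFrame(rows).T

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "heads": {
                k: {
                    "mean_accuracy": s.mean_accuracy,
                    "per_class_accuracy": [None if np.isnan(v) else float(v)
                                           for v in s.per_class_accuracy],
                    "mean_switches": s.mean_switches,
                    "sd_switches": s.sd_switches,
                    "patient_ids": s.patient_ids,
                    "per_patient_accuracy": s.per_patient_accuracy.tolist(),
                    "per_video_switches": s.per_video_switches.tolist(),
                    "confusion_percent": np.where(np.isnan(s.confusion), None,
                                                  s.confusion).tolist(),
                }
                for k, s in self.heads.items()
            },
            "wilcoxon": {
                name: {"statistic": (None if np.isnan(r.statistic) else r.statistic),
                       "p_value": r.p_value, "n_nonzero": r.n_nonzero,
                       "degenerate": r.degenerate}
                for name, r in self.pairwise_p.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _train_group_kinds(head_kinds: Sequence[str]) -> dict[str, list[str]]:
    """Map each trained model to the head variants it serves.

    ``fc`` and ``fc_avg`` share one trained FC model (the averaged head is
    the FC classifier with an output filter); recurrent heads train their
    own models.
    """
    groups: dict[str, list[str]] = {}
    for kind in head_kinds:
        if kind not in HEAD_KINDS:
            raise ValueError(f"unknown head kind {kind!r}")
        trained = "fc" if kind in ("fc", "fc_avg") else kind
        groups.setdefault(trained, []).append(kind)
    return groups


def run_cross_validation(dataset: Sequence[PullbackVideo], head_kinds: Sequence[str],
                         model_spec: ModelSpec, train_cfg: TrainConfig, k: int,
                         seed: int, cmap: CorrespondenceMap | None = None,
                         verbose: bool = False,
                         collect_tracks: bool = False) -> ExperimentReport:
    """Train and evaluate every requested head under k-fold patient CV.

    For each fold, each head is trained on the out-of-fold patients and
    stream-predicts every in-fold video.  Accuracy uses the correspondence
    map over informative frames, pooled per patient across that patient's
    videos; stability counts label switches over all frames of each video.
    """
    cmap = cmap or CorrespondenceMap()
    patients = sorted({v.patient_id for v in dataset})
    if len(patients) < k:
        raise ValueError("dataset must span at least k patients")
    folds = make_folds(patients, k, seed)
    ss = np.random.SeedSequence(seed)

    # per head: patient -> (pred tracks, truths); video scores
    per_head_patient: dict[str, dict[str, list]] = {h: {} for h in head_kinds}
    per_head_video: dict[str, dict[str, int]] = {h: {} for h in head_kinds}
    tracks: dict[str, dict[str, np.ndarray]] = {}
    if collect_tracks:
        tracks = {v.video_id: {"truth": v.labels.copy()} for v in dataset}

    groups = _train_group_kinds(head_kinds)
    for fold in range(k):
        trainset = [v for v in dataset if folds[v.patient_id] != fold]
        testset = [v for v in dataset if folds[v.patient_id] == fold]
        for gi, (trained_kind, variants) in enumerate(sorted(groups.items())):
            child = np.random.SeedSequence((seed, fold, gi))
            init_seed, train_seed = (int(s) % 2**31 for s in child.generate_state(2))
            spec = replace(model_spec, head_kind=trained_kind)
            model = TissueClassifier(spec, seed=init_seed)
            cfg = replace(train_cfg, seed=train_seed)
            if verbose:
                print(f"[fold {fold + 1}/{k}] training {trained_kind} "
                      f"({model.parameter_count} parameters)")
            train(model, trainset, cfg)
            for video in testset:
                for variant in variants:
                    pred = predict_track(model, video, variant,
                                         avg_window=model_spec.avg_window)
                    per_head_video[variant][video.video_id] = count_label_switches(pred)
                    if collect_tracks:
                        tracks[video.video_id][variant] = pred.labels.copy()
                    entry = per_head_patient[variant].setdefault(
                        video.patient_id, {"pred": [], "truth": [], "mask": []})
                    entry["pred"].append(pred.labels)
                    entry["truth"].append(video.labels)
                    entry["mask"].append(video.informative)

    heads: dict[str, HeadSummary] = {}
    for kind in head_kinds:
        pids = sorted(per_head_patient[kind])
        accs, class_accs, pairs = [], [], []
        for pid in pids:
            entry = per_head_patient[kind][pid]
            pred = np.concatenate(entry["pred"])
            truth = np.concatenate(entry["truth"])
            mask = np.concatenate(entry["mask"])
            accs.append(label_accuracy(pred, truth, cmap=cmap, mask=mask))
            class_accs.append(per_class_accuracy(pred, truth, cmap=cmap, mask=mask))
            pairs.append((pred, truth))
        vids = sorted(per_head_video[kind])
        heads[kind] = HeadSummary(
            head_kind=kind,
            patient_ids=pids,
            per_patient_accuracy=np.array(accs),
            per_video_switches=np.array([per_head_video[kind][v] for v in vids]),
            per_class_accuracy=np.nanmean(np.vstack(class_accs), axis=0),
            confusion=confusion_matrix(pairs),
        )

    pairwise: dict[str, WilcoxonResult] = {}
    kinds = list(head_kinds)
    for i, a in enumerate(kinds):
        for b in kinds[i + 1:]:
            pa = dict(zip(heads[a].patient_ids, heads[a].per_patient_accuracy))
            pb = dict(zip(heads[b].patient_ids, heads[b].per_patient_accuracy))
            shared = sorted(set(pa) & set(pb))
            pairwise[f"{a}_vs_{b}"] = wilcoxon_signed_rank(
                [(pa[p], pb[p]) for p in shared])

    return ExperimentReport(heads=heads, pairwise_p=pairwise, k=k, seed=seed,
                            tracks=tracks)
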