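# pullbacknet

Temporally stable tissue classification for esophageal endoscopic
**pullback video**.

During a pullback the endoscope is withdrawn smoothly from the stomach to
healthy squamous esophagus, so five tissue classes appear in fixed
anatomical order — stomach (St), transition Z-line (Tz), Barrett (B),
transition squamous (Ts), squamous (Sq).  Computer-aided detection systems
for Barrett's neoplasia are validated on Barrett-segment images only;
applied naively to a whole procedure they fire outside their domain.  A
stable per-frame *tissue* classifier acts as a gate: downstream lesion
detection runs only while Barrett tissue is in view.  The catch is that
frame-independent classifiers flicker on ambiguous frames (transition
zones, blur, bubbles), and every label flicker toggles the gate.

This package implements, trains and evaluates four classifiers that share
one convolutional feature extractor (four residual blocks, global average
pooling) and differ only in temporal handling:

| head     | temporal mechanism                                           |
|----------|--------------------------------------------------------------|
| `fc`     | none — two fully connected layers, frames independent        |
| `fc_avg` | causal moving average over n = 5 output distributions        |
| `lstm`   | two LSTM layers, hidden state streamed across the video      |
| `gru`    | two GRU layers, hidden state streamed across the video       |

with the training protocol (class/case-balanced sequence sampling,
per-sequence-constant affine augmentation, Adam + cyclic cosine schedule)
and the bespoke evaluation metrics:

* **correspondence-mapped label accuracy** — a prediction is correct when
  the true label lies in its acceptance set (St→{St}, Tz→{Tz,B},
  B→{Tz,B,Ts}, Ts→{B,Ts}, Sq→{Sq}), absorbing transition-zone ambiguity;
  `LabelAcc(L) = (1/Nv) Σ_j TP_j`, averaged unweighted over patients:
  `MeanLabelAccuracy = (1/Np) Σ_i Acc(L_i)`;
* **label-switch stability** — switches of the predicted label between
  consecutive frames, per video; an ideal pullback track switches exactly 4
  times (once per anatomical boundary).

Clinical pullback data are private, so the package ships a **synthetic
pullback generator** (ordered class runs, Barrett-dominant imbalance,
gradual pixel-level transitions with crisp labels, sporadic non-informative
frames) that reproduces the phenomenon at desk scale.  The neural-network
core (convolutions, LSTM/GRU with backpropagation through time, Adam) is
implemented in numpy and verified against finite differences.

## Worked example

```python
from pullbacknet import (CorrespondenceMap, count_label_switches,
                         is_true_positive, label_accuracy)

is_true_positive("B", "Tz")          # True  — Barrett accepts the Z-line zone
is_true_positive("St", "Sq")         # False — stomach never matches squamous

pred, truth = ["B"] * 4, ["Tz", "B", "Ts", "Sq"]
label_accuracy(pred, truth)          # 0.75 (mapped)
label_accuracy(pred, truth, cmap=CorrespondenceMap.identity())   # 0.25 (plain)

ideal = ["St"]*13 + ["Tz"]*15 + ["B"]*47 + ["Ts"]*21 + ["Sq"]*4
count_label_switches(ideal)          # 4 — one switch per anatomical boundary
```

Training and comparing heads end to end (`examples/05_head_comparison.py`
is a 4-minute miniature; numbers below are from the full desk-scale run of
`scripts/acceptance.py --seed 1`: 20 synthetic patients, 100 frames each,
5-fold patient-level CV):

```
label switches per video (ideal = 4)      mean mapped accuracy (%)
  fc       26.95                            fc       91.9
  fc_avg    6.05                            fc_avg   89.7
  lstm      5.55                            lstm     88.0
  gru       6.85                            gru      91.1
```

The stability result is decisive: the frame-independent head flickers
roughly 27 times per video while the smoothed and recurrent heads sit near
the ideal 4, and Wilcoxon signed-rank tests on matched per-patient
accuracies accompany every pairwise comparison.  On accuracy the
frame-independent head keeps a small edge in this desk-scale
configuration: with 100-frame videos the terminal squamous segment spans
only ~4 blended frames, and a recurrent head rarely learns to abandon its
long-accumulated hidden state that quickly within the short training
budget (`docs/methods.md` discusses this limitation in detail — on the
clinical-scale protocol the recurrent heads are reported more accurate as
well as more stable).

A command-line interface wraps the same library:

```bash
pullbacknet simulate --out data/ --n-patients 10 --seed 0
pullbacknet train --data data/ --head lstm --out lstm.npz --seed 0
pullbacknet evaluate --pred preds.csv --truth data/labels.csv --out report.json
pullbacknet experiment --data data/ --heads fc,fc_avg,lstm,gru --k 5 --out report/
```

See `examples/` for narrative scripts covering the generator, training,
metrics, smoothing/streaming, and the head comparison; `docs/methods.md`
documents the model, protocol, generator and their limitations.

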