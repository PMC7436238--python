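"""Train the frame-independent (FC) head on clean synthetic data.

With transitions and noise switched off, the five tissue textures are
cleanly separable, so a few hundred iterations of the balanced-sampling
training loop reach near-perfect held-out accuracy.  Runs in ~20 s on CPU.
"""

import numpy as np

from pullbacknet import (
    CorrespondenceMap,
    ModelSpec,
    SyntheticConfig,
    TissueClassifier,
    TrainConfig,
    decode_labels,
    generate_cohort,
    label_accuracy,
    train,
)

cfg = SyntheticConfig(transition_width=0, noise_sd=0.0, noninformative_rate=0.0)
train_cohort = generate_cohort(cfg, 8, seed=11)
heldout = generate_cohort(cfg, 4, seed=12)

spec = ModelSpec(head_kind="fc", widths=(8, 16, 32, 64), hidden_size=64)
model = TissueClassifier(spec, seed=3)
print(f"FC model: {model.parameter_count} parameters")

history = train(model, train_cohort,
                TrainConfig(batch_sequences=16, base_lr=1e-3,
                            scheduler_period=150, total_iterations=300, seed=5),
                log_every=100)

plain = CorrespondenceMap.identity()
accs = [label_accuracy(decode_labels(model.predict_video(v)), v.labels, cmap=plain)
        for v in heldout]
print(f"held-out frame accuracy over {len(heldout)} unseen patients: "
      f"{np.mean(accs):.3f}")
# Accuracy here uses the identity map (plain per-frame accuracy): on clean
# separable data no transition-ambiguity forgiveness is needed.
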