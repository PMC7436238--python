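"""Training protocol: balanced sampling, sequence drawing, constant-affine
augmentation, the cosine schedule, and end-to-end learning."""

import numpy as np
import pytest

from pullbacknet.frames import PullbackVideo
from pullbacknet.models import ModelSpec, TissueClassifier, decode_labels
from pullbacknet.metrics import CorrespondenceMap, label_accuracy
from pullbacknet.synthetic import SyntheticConfig, generate_cohort
from pullbacknet.training import (
    AugmentConfig,
    TrainConfig,
    augment_sequence,
    compute_sampling_weights,
    cyclic_cosine_lr,
    draw_batch,
    sample_affine_matrix,
    apply_affine,
    train,
)


def make_video(patient_id, video_id, labels, informative=None, size=8):
    T = len(labels)
    rng = np.random.default_rng(hash((patient_id, video_id)) % 2**31)
    return PullbackVideo(
        patient_id=patient_id,
        video_id=video_id,
        images=rng.uniform(0, 1, size=(T, size, size, 3)).astype(np.float32),
        labels=np.asarray(labels),
        informative=np.ones(T, bool) if informative is None else np.asarray(informative),
    )


class TestSamplingWeights:
    def test_two_class_closed_form(self):
        """1 case, classes with 10 and 30 eligible frames: weights 1/(2*10), 1/(2*30)."""
        video = make_video("A", "A_v0", [0] * 10 + [2] * 30)
        w = compute_sampling_weights([video], sequence_length=1)
        probs = np.zeros(40)
        probs[w.position] = w.probability
        assert np.allclose(probs[:10], 1 / 20)
        assert np.allclose(probs[10:], 1 / 60)
        assert probs[:10].sum() == pytest.approx(0.5)
        assert probs[10:].sum() == pytest.approx(0.5)

    def test_two_cases_equal_mass(self):
        videos = [make_video("A", "A_v0", [2] * 7), make_video("B", "B_v0", [2] * 23)]
        w = compute_sampling_weights(videos, sequence_length=1)
        mass_a = w.probability[w.video_index == 0].sum()
        mass_b = w.probability[w.video_index == 1].sum()
        assert mass_a == pytest.approx(0.5)
        assert mass_b == pytest.approx(0.5)

    def test_single_cell_uniform(self):
        video = make_video("A", "A_v0", [1] * 12)
        w = compute_sampling_weights([video], sequence_length=1)
        assert np.allclose(w.probability, 1.0 / 12)

    def test_cell_masses_exactly_equal(self):
        videos = [
            make_video("A", "A_v0", [0] * 3 + [1] * 9 + [2] * 20),
            make_video("B", "B_v0", [2] * 5 + [3] * 6),
        ]
        w = compute_sampling_weights(videos, sequence_length=1)
        cells = {}
        for vi, t, p in zip(w.video_index, w.position, w.probability):
            key = (videos[vi].patient_id, int(videos[vi].labels[t]))
            cells[key] = cells.get(key, 0.0) + p
        assert len(cells) == 5
        for mass in cells.values():
            assert mass == pytest.approx(1.0 / 5)

    def test_ineligible_frames_excluded(self):
        informative = [True] * 9 + [False]
        video = make_video("A", "A_v0", [2] * 10, informative)
        w = compute_sampling_weights([video], sequence_length=4)
        # positions 0..2 lack 3 predecessors; position 9 is non-informative
        assert set(w.position) == {3, 4, 5, 6, 7, 8}

    def test_all_ineligible_errors(self):
        video = make_video("A", "A_v0", [2] * 5, [False] * 5)
        with pytest.raises(ValueError, match="eligible"):
            compute_sampling_weights([video], sequence_length=1)


class TestDrawBatch:
    def test_sequences_are_consecutive_and_end_informative(self, rng):
        informative = np.ones(30, bool)
        informative[::5] = False
        video = make_video("A", "A_v0", [2] * 30, informative)
        w = compute_sampling_weights([video], sequence_length=4)
        batch = draw_batch([video], w, 8, rng)
        assert batch.images.shape == (8, 4, 8, 8, 3)
        for b in range(8):
            end = batch.end_position[b]
            assert informative[end]
            expected = video.images[end - 3:end + 1]
            assert np.array_equal(batch.images[b], expected)

    def test_length_one_draws_single_frames(self, rng):
        video = make_video("A", "A_v0", [0] * 4 + [1] * 4 + [2] * 4 + [3] * 4 + [4] * 4)
        w = compute_sampling_weights([video], sequence_length=1)
        batch = draw_batch([video], w, 16, rng)
        assert batch.images.shape[1] == 1
        assert np.array_equal(batch.targets,
                              video.labels[batch.end_position])

    def test_target_class_frequency_uniform(self, rng):
        """Heavily imbalanced data, 50,000 draws: targets uniform within 2%."""
        videos = [
            make_video("A", "A_v0", [0] * 5 + [1] * 10 + [2] * 200 + [3] * 30 + [4] * 5),
            make_video("B", "B_v0", [0] * 50 + [1] * 3 + [2] * 100 + [3] * 3 + [4] * 3),
        ]
        w = compute_sampling_weights(videos, sequence_length=1)
        batch = draw_batch(videos, w, 50_000, rng)
        freq = np.bincount(batch.targets, minlength=5) / 50_000
        assert np.abs(freq - 0.2).max() <= 0.02


class TestAugmentation:
    def test_zero_magnitudes_is_identity(self, rng):
        seq = rng.uniform(0, 1, size=(3, 16, 16, 3))
        out = augment_sequence(seq, AugmentConfig(0.0, 0.0, 0.0), rng)
        assert np.array_equal(out, seq)

    def test_same_transform_for_all_frames(self, rng):
        """Two identical frames in one sequence stay identical after augmentation."""
        frame = rng.uniform(0, 1, size=(16, 16, 3))
        seq = np.stack([frame, frame, frame])
        out = augment_sequence(seq, AugmentConfig(), rng)
        assert np.array_equal(out[0], out[1])
        assert np.array_equal(out[1], out[2])

    def test_rigidity_on_coordinate_grid(self, rng):
        """Pixelwise: every frame receives the same affine map (checked by
        applying the sampled map to a coordinate grid)."""
        H = W = 16
        matrix, offset = sample_affine_matrix((H, W), AugmentConfig(), rng)
        grid = np.stack(np.meshgrid(np.arange(H), np.arange(W), indexing="ij"),
                        axis=-1).astype(float)
        grid = np.concatenate([grid, np.zeros((H, W, 1))], axis=-1) / max(H, W)
        seq = np.stack([grid, grid])
        out = apply_affine(seq, matrix, offset)
        assert np.array_equal(out[0], out[1])

    def test_seeded_determinism(self):
        seq = np.random.default_rng(0).uniform(0, 1, size=(2, 16, 16, 3))
        a = augment_sequence(seq, AugmentConfig(), np.random.default_rng(42))
        b = augment_sequence(seq, AugmentConfig(), np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestCosineSchedule:
    def test_anchor_points(self):
        assert cyclic_cosine_lr(0, 1e-4, 100) == pytest.approx(1e-4)
        assert cyclic_cosine_lr(50, 1e-4, 100) == pytest.approx(5e-5)
        assert cyclic_cosine_lr(100, 1e-4, 100) == pytest.approx(1e-4)  # restart

    def test_monotone_within_cycle(self):
        lrs = [cyclic_cosine_lr(i, 1.0, 50) for i in range(50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestTrainLoop:
    def test_zero_iterations_is_noop(self, separable_cohort, small_spec):
        model = TissueClassifier(small_spec, seed=0)
        before = [p.value.copy() for p in model.parameters()]
        hist = train(model, separable_cohort,
                     TrainConfig(total_iterations=0, batch_sequences=4))
        assert hist.loss == []
        for p, old in zip(model.parameters(), before):
            assert np.array_equal(p.value, old)

    def test_seeded_determinism(self, separable_cohort, small_spec):
        cfg = TrainConfig(total_iterations=12, batch_sequences=4, base_lr=1e-3,
                          scheduler_period=10, seed=7)
        h1 = train(TissueClassifier(small_spec, seed=0), separable_cohort, cfg)
        h2 = train(TissueClassifier(small_spec, seed=0), separable_cohort, cfg)
        assert h1.loss == h2.loss

    def test_fc_learns_separable_cohort(self, separable_cfg, separable_cohort):
        """300 iterations on clean separable data: held-out accuracy > 0.9."""
        spec = ModelSpec(head_kind="fc", widths=(8, 16, 32, 64), hidden_size=64)
        model = TissueClassifier(spec, seed=3)
        cfg = TrainConfig(batch_sequences=16, base_lr=1e-3, scheduler_period=150,
                          total_iterations=300, seed=5)
        hist = train(model, separable_cohort, cfg)
        heldout = generate_cohort(separable_cfg, 4, seed=12)
        ident = CorrespondenceMap.identity()
        accs = [label_accuracy(decode_labels(model.predict_video(v)), v.labels,
                               cmap=ident) for v in heldout]
        assert np.mean(accs) > 0.9
        # loss trend: median of the last tenth below the first tenth
        tenth = len(hist.loss) // 10
        assert np.median(hist.loss[-tenth:]) < np.median(hist.loss[:tenth])
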