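"""Model contracts: feature extraction, the four heads, streaming state,
causal averaging, decoding, persistence."""

import numpy as np
import pytest

from pullbacknet.frames import ClassProbTrack
from pullbacknet.models import (
    ModelSpec,
    RecurrentState,
    TissueClassifier,
    causal_average,
    decode_labels,
)


@pytest.fixture
def images(rng):
    return rng.uniform(0, 1, size=(10, 32, 32, 3))


def test_extract_features_shape_and_finiteness(small_spec, images):
    model = TissueClassifier(small_spec, seed=0)
    feats = model.extract_features(images)
    assert feats.shape == (10, small_spec.feature_dim)
    assert np.all(np.isfinite(feats))
    assert np.all(np.isfinite(model.extract_features(np.zeros((2, 32, 32, 3)))))


def test_features_independent_of_batch_composition(small_spec, images):
    model = TissueClassifier(small_spec, seed=0)
    whole = model.extract_features(images)
    alone = model.extract_features(images[3:4])
    assert np.allclose(whole[3], alone[0], atol=1e-5)


def test_wrong_spatial_size_errors(small_spec, rng):
    model = TissueClassifier(small_spec, seed=0)
    with pytest.raises(ValueError, match="expects"):
        model.extract_features(rng.uniform(0, 1, size=(2, 16, 16, 3)))


@pytest.mark.parametrize("kind", ["fc", "fc_avg", "lstm", "gru"])
def test_head_rows_on_simplex(kind, rng):
    spec = ModelSpec(head_kind=kind, widths=(4, 8, 8, 16), hidden_size=16)
    model = TissueClassifier(spec, seed=1)
    feats = rng.standard_normal((7, spec.feature_dim))
    track, _ = model.head_forward(feats)
    assert track.probs.shape == (7, 5)
    assert np.all(track.probs >= 0)
    assert np.allclose(track.probs.sum(axis=1), 1.0, atol=1e-6)


def test_fc_head_is_frame_independent(small_spec, rng):
    model = TissueClassifier(small_spec, seed=1)
    feats = rng.standard_normal((6, small_spec.feature_dim))
    perm = rng.permutation(6)
    base, _ = model.head_forward(feats)
    permuted, _ = model.head_forward(feats[perm])
    assert np.allclose(base.probs[perm], permuted.probs, atol=1e-6)


@pytest.mark.parametrize("kind", ["lstm", "gru"])
def test_recurrent_chunked_equals_whole(kind, rng):
    """Processing 10 rows at once equals 5 + 5 with the carried state."""
    spec = ModelSpec(head_kind=kind, widths=(4, 8, 8, 16), hidden_size=16)
    model = TissueClassifier(spec, seed=2)
    feats = rng.standard_normal((10, spec.feature_dim))
    whole, state_w = model.head_forward(feats)
    first, state = model.head_forward(feats[:5])
    second, state2 = model.head_forward(feats[5:], state)
    chunked = np.vstack([first.probs, second.probs])
    assert np.abs(whole.probs - chunked).max() < 1e-5
    for a, b in zip(state_w.layers, state2.layers):
        arrs_a = a if kind == "lstm" else (a,)
        arrs_b = b if kind == "lstm" else (b,)
        for x, y in zip(arrs_a, arrs_b):
            assert np.abs(x - y).max() < 1e-5


def test_recurrent_state_validation(rng):
    lstm_spec = ModelSpec(head_kind="lstm", widths=(4, 8, 8, 16), hidden_size=16)
    gru_spec = ModelSpec(head_kind="gru", widths=(4, 8, 8, 16), hidden_size=16)
    model = TissueClassifier(lstm_spec, seed=0)
    wrong = RecurrentState.zeros(gru_spec)
    with pytest.raises(ValueError, match="state kind"):
        model.head_forward(rng.standard_normal((3, 16)), wrong)


def test_fc_avg_with_window_one_matches_fc(rng, images):
    """Same weights, avg_window=1: the averaged head decodes exactly like FC."""
    fc = TissueClassifier(ModelSpec(head_kind="fc", widths=(4, 8, 8, 16),
                                    hidden_size=16), seed=5)
    fc_avg = TissueClassifier(ModelSpec(head_kind="fc_avg", widths=(4, 8, 8, 16),
                                        hidden_size=16, avg_window=1), seed=5)
    a = decode_labels(fc.predict_video(images))
    b = decode_labels(fc_avg.predict_video(images))
    assert np.array_equal(a.labels, b.labels)


def test_causal_average_identity_and_constant():
    track = ClassProbTrack(probs=np.tile([0.2, 0.2, 0.2, 0.2, 0.2], (6, 1)))
    assert np.allclose(causal_average(track, 1).probs, track.probs)
    assert np.allclose(causal_average(track, 4).probs, track.probs)


def test_causal_average_hand_computed_window():
    """One-hot A,A,A,A,A,B,A,A,A,A with n=5: B mass peaks at 1/5, argmax stays A."""
    onehot = np.zeros((10, 5))
    onehot[:, 0] = 1.0
    onehot[5] = [0, 0, 1, 0, 0]
    smoothed = causal_average(ClassProbTrack(probs=onehot), 5)
    # hand-computed: rows 5..9 contain exactly one B frame in their window
    for t in range(10):
        window = onehot[max(0, t - 4):t + 1]
        assert np.allclose(smoothed.probs[t], window.mean(axis=0))
    assert smoothed.probs[:, 2].max() == pytest.approx(0.2)
    assert np.all(decode_labels(smoothed).labels == 0)
    assert np.allclose(smoothed.probs.sum(axis=1), 1.0)


def test_causal_average_rejects_empty_and_bad_window():
    track = ClassProbTrack(probs=np.zeros((0, 5)))
    with pytest.raises(ValueError):
        causal_average(track, 5)
    with pytest.raises(ValueError):
        causal_average(ClassProbTrack(probs=np.ones((2, 5)) / 5), 0)


def test_decode_labels_argmax_and_tiebreak():
    probs = np.array([
        [0, 0, 1, 0, 0],
        [0.2, 0.2, 0.2, 0.2, 0.2],  # tie -> earliest class (St)
        [0.1, 0.5, 0.1, 0.2, 0.1],
    ])
    track = decode_labels(ClassProbTrack(probs=probs))
    assert track.names == ["B", "St", "Tz"]


def test_decode_is_pointwise():
    p1 = np.eye(5)
    p2 = np.eye(5)[::-1].copy()
    a = decode_labels(ClassProbTrack(probs=p1)).labels
    b = decode_labels(ClassProbTrack(probs=p2)).labels
    both = decode_labels(ClassProbTrack(probs=np.vstack([p1, p2]))).labels
    assert np.array_equal(both, np.concatenate([a, b]))


@pytest.mark.parametrize("kind,expected", [
    # head parameter counts for hidden=128, D=128, 5 classes, 2 layers
    ("fc", 128 * 128 + 128 + 128 * 5 + 5),
    ("lstm", 2 * (4 * 128 * 128 + 4 * 128 * 128 + 4 * 128) + 128 * 5 + 5),
    ("gru", 2 * (3 * 128 * 128 + 3 * 128 * 128 + 2 * 3 * 128) + 128 * 5 + 5),
])
def test_head_parameter_counts(kind, expected):
    spec = ModelSpec(head_kind=kind)
    model = TissueClassifier(spec, seed=0)
    extractor_params = sum(
        p.value.size for blk in model.blocks for p in blk.parameters())
    assert model.parameter_count - extractor_params == expected


def test_checkpoint_roundtrip(tmp_path, small_spec, images):
    model = TissueClassifier(small_spec, seed=3)
    path = tmp_path / "model.npz"
    model.save(path)
    clone = TissueClassifier.load(path)
    assert clone.spec == model.spec
    a = model.predict_video(images)
    b = clone.predict_video(images)
    assert np.array_equal(a.probs, b.probs)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(head_kind="transformer")
    with pytest.raises(ValueError):
        ModelSpec(image_size=(8, 8))
    with pytest.raises(ValueError):
        ModelSpec(hidden_size=0)
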