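"""Feature extractor and classifier heads for per-frame tissue classification.

The model has two stages.  A small fully-convolutional residual network
(four basic blocks, global average pooling) maps each frame to a feature
vector.  On top of that sit four interchangeable classifier heads:

``fc``
    two fully connected layers with a ReLU in between; frames are
    classified independently.
``fc_avg``
    the same FC head, but at inference its per-frame probability rows are
    smoothed with a causal moving average over ``avg_window`` frames.
``lstm`` / ``gru``
    two recurrent layers (hidden size 128 by default) followed by a fully
    connected layer; the hidden state carries context from earlier frames,
    so a whole pullback video can be processed as a stream.

The averaging window is causal (past frames only): the system is intended
for live video, where future frames are not available.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .frames import N_CLASSES, ClassProbTrack, LabelTrack, PullbackVideo

HEAD_KINDS = ("fc", "fc_avg", "lstm", "gru")


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    ``widths`` are the channel counts of the four convolutional blocks; the
    feature dimension equals ``widths[-1]``.  Each block downsamples by 2,
    so the smallest supported input side is 16 pixels.
    """

    head_kind: str = "fc"
    image_size: tuple[int, int] = (32, 32)
    widths: tuple[int, int, int, int] = (16, 32, 64, 128)
    hidden_size: int = 128
    recurrent_layers: int = 2
    avg_window: int = 5
    n_classes: int = N_CLASSES
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.image_size = tuple(self.image_size)  # type: ignore[assignment]
        self.widths = tuple(self.widths)  # type: ignore[assignment]
        if self.head_kind not in HEAD_KINDS:
            raise ValueError(f"head_kind must be one of {HEAD_KINDS}, got {self.head_kind!r}")
        if len(self.widths) != 4:
            raise ValueError("widths must list four block widths")
        if self.hidden_size < 1 or self.recurrent_layers < 1 or self.avg_window < 1:
            raise ValueError("hidden_size, recurrent_layers and avg_window must be >= 1")
        if min(self.image_size) < 16:
            raise ValueError("image sides must be >= 16 pixels (four stride-2 blocks)")

    @property
    def feature_dim(self) -> int:
        return self.widths[-1]

    @property
    def recurrent(self) -> bool:
        return self.head_kind in ("lstm", "gru")

    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


@dataclass
class RecurrentState:
    """Per-layer hidden (and, for LSTM, cell) activations of one video stream."""

    kind: str  # "lstm" or "gru"
    layers: list  # LSTM: [(h, c), ...]; GRU: [h, ...]

    @classmethod
    def zeros(cls, spec: ModelSpec, batch: int = 1) -> "RecurrentState":
        dt = spec.np_dtype()
        shape = (batch, spec.hidden_size)
        if spec.head_kind == "lstm":
            layers = [(np.zeros(shape, dt), np.zeros(shape, dt))
                      for _ in range(spec.recurrent_layers)]
        elif spec.head_kind == "gru":
            layers = [np.zeros(shape, dt) for _ in range(spec.recurrent_layers)]
        else:
            raise ValueError(f"head {spec.head_kind!r} is stateless")
        return cls(kind=spec.head_kind, layers=layers)

    def validate(self, spec: ModelSpec) -> None:
        if self.kind != spec.head_kind:
            raise ValueError(f"state kind {self.kind!r} does not match head {spec.head_kind!r}")
        if len(self.layers) != spec.recurrent_layers:
            raise ValueError("state layer count does not match spec")
        for entry in self.layers:
            arrs = entry if self.kind == "lstm" else (entry,)
            for a in arrs:
                if a.shape[-1] != spec.hidden_size:
                    raise ValueError("state width does not match spec.hidden_size")


class TissueClassifier(nn.Module):
    """Extractor + head, with training-time backprop and streaming inference."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        dt = spec.np_dtype()
        rng = np.random.default_rng(seed)
        w = spec.widths
        self.blocks = [
            nn.BasicBlock(3, w[0], stride=2, rng=rng, dtype=dt),
            nn.BasicBlock(w[0], w[1], stride=2, rng=rng, dtype=dt),
            nn.BasicBlock(w[1], w[2], stride=2, rng=rng, dtype=dt),
            nn.BasicBlock(w[2], w[3], stride=2, rng=rng, dtype=dt),
        ]
        self.pool = nn.GlobalAvgPool()
        D = spec.feature_dim
        if spec.head_kind in ("fc", "fc_avg"):
            self.fc1 = nn.Linear(D, spec.hidden_size, rng=rng, dtype=dt)
            self.fc_relu = nn.ReLU()
            self.fc2 = nn.Linear(spec.hidden_size, spec.n_classes, rng=rng, dtype=dt)
        elif spec.head_kind == "lstm":
            self.rnn = nn.LSTM(D, spec.hidden_size, spec.recurrent_layers, rng=rng, dtype=dt)
            self.out = nn.Linear(spec.hidden_size, spec.n_classes, rng=rng, dtype=dt)
        else:
            self.rnn = nn.GRU(D, spec.hidden_size, spec.recurrent_layers, rng=rng, dtype=dt)
            self.out = nn.Linear(spec.hidden_size, spec.n_classes, rng=rng, dtype=dt)

    # ---------------------------------------------------------------- features

    def _check_size(self, H: int, W: int) -> None:
        if (H, W) != tuple(self.spec.image_size):
            raise ValueError(
                f"frames are {H}x{W} but the model expects "
                f"{self.spec.image_size[0]}x{self.spec.image_size[1]}"
            )

    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError(f"expected (N, H, W, 3) images, got {images.shape}")
        self._check_size(images.shape[1], images.shape[2])
        return np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=self.spec.np_dtype())

    def _extractor_forward(self, x_nchw: np.ndarray) -> np.ndarray:
        h = x_nchw
        for blk in self.blocks:
            h = blk.forward(h)
        return self.pool.forward(h)

    def _extractor_backward(self, dfeat: np.ndarray) -> None:
        d = self.pool.backward(dfeat)
        for blk in reversed(self.blocks):
            d = blk.backward(d)

    def extract_features(self, images: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Map ``(N, H, W, 3)`` frames to ``(N, D)`` features (inference only).

        Per-frame results are independent of batch composition; frames are
        processed in chunks to bound memory.
        """
        x = self._to_nchw(images)
        outs = [self._extractor_forward(x[i:i + chunk]) for i in range(0, x.shape[0], chunk)]
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, self.spec.feature_dim))

    # ------------------------------------------------------------------- heads

    def _fc_logits(self, feats: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.fc_relu.forward(self.fc1.forward(feats)))

    def _fc_backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.fc_relu.backward(self.fc2.backward(dlogits)))

    def head_forward(
        self, features: np.ndarray, state: RecurrentState | None = None
    ) -> tuple[ClassProbTrack, RecurrentState | None]:
        """Turn ordered feature rows ``(T, D)`` into per-frame class probabilities.

        FC heads ignore ``state``; recurrent heads treat ``None`` as the
        all-zero state and return the updated state, so a video can be
        processed chunk-by-chunk as a stream.
        """
        features = np.asarray(features, dtype=self.spec.np_dtype())
        if features.ndim != 2 or features.shape[1] != self.spec.feature_dim:
            raise ValueError(f"expected (T, {self.spec.feature_dim}) features")
        if not self.spec.recurrent:
            probs = nn.softmax(self._fc_logits(features))
            return ClassProbTrack(probs=probs), None
        if state is not None:
            state.validate(self.spec)
        nn_state = None if state is None else state.layers
        y, new_state = self.rnn.forward(features[None, :, :], nn_state)
        logits = self.out.forward(y[0])
        probs = nn.softmax(logits)
        return ClassProbTrack(probs=probs), RecurrentState(self.spec.head_kind, new_state)

    # ---------------------------------------------------------------- training

    def train_step_backward(self, images: np.ndarray, targets: np.ndarray,
                            supervise_all: bool = False) -> float:
        """Forward + backward for one batch of sequences.

        ``images``: (B, L, H, W, 3); ``targets``: (B,) class index of the
        final frame of each sequence.  Recurrent heads consume the L-frame
        sequence from the all-zero state; the loss is taken on the final
        frame's prediction (or on every frame when ``supervise_all``).
        Gradients are accumulated into the parameters; returns the loss.
        """
        B, L = images.shape[:2]
        flat = images.reshape(B * L, *images.shape[2:])
        feats = self._extractor_forward(self._to_nchw(flat))  # (B*L, D)
        D = self.spec.feature_dim
        if not self.spec.recurrent:
            # frame-independent head: supervise the final frame of each sequence
            idx = np.arange(B) * L + (L - 1)
            logits = self._fc_logits(feats[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, targets)
            dfeats_sel = self._fc_backward(dlogits)
            dfeats = np.zeros_like(feats)
            dfeats[idx] = dfeats_sel
        else:
            seq = feats.reshape(B, L, D)
            y, _ = self.rnn.forward(seq, None)
            if supervise_all:
                logits = self.out.forward(y.reshape(B * L, -1))
                tgt = np.repeat(targets, L)
                loss, dlogits = nn.softmax_cross_entropy(logits, tgt)
                dy = self.out.backward(dlogits).reshape(B, L, -1)
            else:
                logits = self.out.forward(y[:, -1])
                loss, dlogits = nn.softmax_cross_entropy(logits, targets)
                dy_last = self.out.backward(dlogits)
                dy = np.zeros_like(y)
                dy[:, -1] = dy_last
            dfeats = self.rnn.backward(dy).reshape(B * L, D)
        self._extractor_backward(dfeats)
        return loss

    # --------------------------------------------------------------- inference

    def predict_video(self, video: PullbackVideo | np.ndarray,
                      reset_interval: int | None = None) -> ClassProbTrack:
        """Class-probability track for a whole video.

        Recurrent heads stream the video with the hidden state carried from
        the first frame to the last (``reset_interval`` re-zeros the state
        every that many frames, mimicking windowed inference).  The
        ``fc_avg`` head applies the causal averaging filter.
        """
        images = video.images if isinstance(video, PullbackVideo) else video
        fidx = video.frame_index if isinstance(video, PullbackVideo) else None
        feats = self.extract_features(images)
        if not self.spec.recurrent:
            track, _ = self.head_forward(feats)
            if self.spec.head_kind == "fc_avg":
                track = causal_average(track, self.spec.avg_window)
        else:
            T = feats.shape[0]
            step = reset_interval or T
            rows = []
            for start in range(0, T, step):
                chunk_track, _ = self.head_forward(feats[start:start + step], None)
                rows.append(chunk_track.probs)
            track = ClassProbTrack(probs=np.concatenate(rows, axis=0))
        if fidx is not None:
            track.frame_index = np.asarray(fidx)
        return track

    # -------------------------------------------------------------- persistence

    @property
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez(path, spec=np.asarray(self.spec.to_json()), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TissueClassifier":
        with np.load(path, allow_pickle=False) as data:
            spec = ModelSpec.from_json(str(data["spec"]))
            model = cls(spec)
            params = model.parameters()
            for i, p in enumerate(params):
                p.value = data[f"param_{i}"].copy()
        return model


def causal_average(track: ClassProbTrack, n: int) -> ClassProbTrack:
    """Causal moving average of probability rows.

    Row ``t`` of the result is the unweighted mean of input rows
    ``max(0, t-n+1)..t`` — the window only looks backwards and is shorter at
    the start of the track.  Averaging convex rows keeps them on the simplex.
    """
    if n < 1:
        raise ValueError("window must be >= 1")
    if len(track) == 0:
        raise ValueError("cannot average an empty track")
    p = track.probs
    csum = np.cumsum(np.vstack([np.zeros((1, p.shape[1])), p]), axis=0)
    t = np.arange(len(track))
    lo = np.maximum(0, t - n + 1)
    counts = (t - lo + 1).astype(float)
    smoothed = (csum[t + 1] - csum[lo]) / counts[:, None]
    return ClassProbTrack(probs=smoothed, frame_index=track.frame_index.copy())


def decode_labels(track: ClassProbTrack) -> LabelTrack:
    """Per-row argmax; ties resolve to the earliest class in pullback order."""
    return LabelTrack(labels=np.argmax(track.probs, axis=1),
                      frame_index=track.frame_index.copy())
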