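"""Training protocol: balanced sequence sampling, per-sequence-constant
affine augmentation, Adam with a cyclic cosine learning-rate schedule.

The sampler undoes the heavy class imbalance of pullback data (Barrett
dominates) and the unequal video lengths: every frame receives a weight so
that the probability of drawing each (patient case, tissue class) cell is
equal, and frames within a cell are drawn uniformly.  Sequences are
addressed by their final frame, which must be informative; earlier frames
of a sequence may be non-informative — that is precisely the context a
recurrent head should learn to ride through.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .frames import PullbackVideo
from .models import TissueClassifier
from .nn import Adam


@dataclass
class AugmentConfig:
    """Random-affine augmentation bounds (identity when all zero)."""

    max_rotation_deg: float = 5.0
    translate_crop_frac: float = 0.025
    max_shear_deg: float = 5.0

    @property
    def is_identity(self) -> bool:
        return self.max_rotation_deg == 0 and self.translate_crop_frac == 0 and self.max_shear_deg == 0


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``sequence_length`` is 1 for frame-independent (FC) heads and 10 for
    recurrent heads; ``None`` selects automatically from the model spec.
    """

    sequence_length: int | None = None
    batch_sequences: int = 512
    base_lr: float = 1e-4
    scheduler_period: int = 500
    total_iterations: int = 2000
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    supervise_all: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.augment, dict):
            self.augment = AugmentConfig(**self.augment)
        if self.sequence_length is not None and self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.batch_sequences < 1:
            raise ValueError("batch_sequences must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be > 0")
        if self.scheduler_period < 1:
            raise ValueError("scheduler_period must be >= 1")

    def resolved_sequence_length(self, recurrent: bool) -> int:
        if self.sequence_length is not None:
            return self.sequence_length
        return 10 if recurrent else 1


@dataclass
class SampleWeights:
    """Per-frame sampling probabilities over a training set.

    ``video_index`` / ``position`` address eligible sequence-final frames;
    ``probability`` sums to 1.  Frames that cannot terminate a valid
    sequence (non-informative, or fewer than L-1 predecessors) carry zero
    mass and are simply absent from the arrays.
    """

    video_index: np.ndarray
    position: np.ndarray
    probability: np.ndarray
    sequence_length: int

    def __post_init__(self) -> None:
        if not math.isclose(self.probability.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("sampling probabilities must sum to 1")
        if np.any(self.probability < 0):
            raise ValueError("sampling probabilities must be non-negative")


def compute_sampling_weights(dataset: Sequence[PullbackVideo],
                             sequence_length: int = 1) -> SampleWeights:
    """Class- and case-balanced sampling weights over sequence-final frames.

    Eligible frames are informative and have at least ``sequence_length-1``
    predecessors within their video.  Probability mass is uniform across
    non-empty (patient case, class) cells and uniform within each cell:
    each eligible frame gets 1 / (n_cells * cell_size).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    vid_idx: list[int] = []
    pos: list[int] = []
    cell_key: list[tuple[str, int]] = []
    for vi, video in enumerate(dataset):
        T = len(video)
        for t in range(sequence_length - 1, T):
            if video.informative[t]:
                vid_idx.append(vi)
                pos.append(t)
                cell_key.append((video.patient_id, int(video.labels[t])))
    if not vid_idx:
        raise ValueError("no eligible frames: every video lacks informative "
                         f"frames with >= {sequence_length - 1} predecessors")
    cells = sorted(set(cell_key))
    cell_sizes = {c: 0 for c in cells}
    for c in cell_key:
        cell_sizes[c] += 1
    n_cells = len(cells)
    prob = np.array([1.0 / (n_cells * cell_sizes[c]) for c in cell_key])
    return SampleWeights(
        video_index=np.asarray(vid_idx),
        position=np.asarray(pos),
        probability=prob,
        sequence_length=sequence_length,
    )


@dataclass
class SequenceBatch:
    images: np.ndarray  # (B, L, H, W, 3)
    targets: np.ndarray  # (B,) class index of the final frame
    video_index: np.ndarray
    end_position: np.ndarray


def draw_batch(dataset: Sequence[PullbackVideo], weights: SampleWeights,
               batch_sequences: int, rng: np.random.Generator) -> SequenceBatch:
    """Draw ``batch_sequences`` length-L windows ending at weighted frames."""
    L = weights.sequence_length
    picks = rng.choice(len(weights.probability), size=batch_sequences,
                       replace=True, p=weights.probability)
    images, targets = [], []
    for k in picks:
        vi, t = int(weights.video_index[k]), int(weights.position[k])
        video = dataset[vi]
        images.append(video.images[t - L + 1:t + 1])
        targets.append(int(video.labels[t]))
    return SequenceBatch(
        images=np.stack(images),
        targets=np.asarray(targets),
        video_index=weights.video_index[picks],
        end_position=weights.position[picks],
    )


def sample_affine_matrix(image_size: tuple[int, int], cfg: AugmentConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random affine map (output->input matrix and offset) about the center.

    Rotation and shear are bounded in degrees; translation and scale (the
    crop) by a fraction of the image side.  All-zero bounds give the exact
    identity.
    """
    H, W = image_size
    theta = math.radians(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    shear = math.radians(rng.uniform(-cfg.max_shear_deg, cfg.max_shear_deg))
    scale = 1.0 + rng.uniform(-cfg.translate_crop_frac, cfg.translate_crop_frac)
    ty = rng.uniform(-cfg.translate_crop_frac, cfg.translate_crop_frac) * H
    tx = rng.uniform(-cfg.translate_crop_frac, cfg.translate_crop_frac) * W
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    shr = np.array([[1.0, math.tan(shear)], [0.0, 1.0]])
    fwd = scale * (rot @ shr)  # forward map in (row, col) coordinates
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    inv = np.linalg.inv(fwd)  # ndimage wants the output->input map
    offset = center - inv @ (center + np.array([ty, tx]))
    return inv, offset


def apply_affine(images: np.ndarray, matrix: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Apply one 2-D affine map to every frame of an (L, H, W, 3) sequence.

    Bilinear resampling with edge clamping, vectorized over the whole
    sequence: the warped coordinate grid is computed once and all frames
    and channels are gathered together.  The identity map reproduces the
    input exactly.
    """
    L, H, W = images.shape[:3]
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    src = matrix @ np.stack([ys.ravel(), xs.ravel()]) + offset[:, None]
    iy = np.clip(src[0], 0.0, H - 1.0)
    ix = np.clip(src[1], 0.0, W - 1.0)
    y0 = np.floor(iy).astype(int)
    x0 = np.floor(ix).astype(int)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    wy = (iy - y0).astype(images.dtype)[None, :, None]
    wx = (ix - x0).astype(images.dtype)[None, :, None]
    flat = images.reshape(L, H * W, -1)
    top = flat[:, y0 * W + x0] * (1 - wx) + flat[:, y0 * W + x1] * wx
    bot = flat[:, y1 * W + x0] * (1 - wx) + flat[:, y1 * W + x1] * wx
    out = (top * (1 - wy) + bot * wy).reshape(images.shape)
    return np.clip(out, 0.0, 1.0)


def augment_sequence(seq: np.ndarray, cfg: AugmentConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Augment an (L, H, W, 3) sequence with ONE affine map for all frames.

    Keeping the transform constant per sequence preserves the temporal
    structure the recurrent heads are meant to learn.
    """
    if seq.shape[0] == 0:
        raise ValueError("empty sequence")
    if cfg.is_identity:
        return seq
    matrix, offset = sample_affine_matrix(seq.shape[1:3], cfg, rng)
    return apply_affine(seq, matrix, offset)


def cyclic_cosine_lr(iteration: int, base_lr: float, period: int) -> float:
    """lr(i) = base_lr * (1 + cos(pi * (i mod period) / period)) / 2.

    Decays from ``base_lr`` toward 0 within each cycle and restarts.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    phase = (iteration % period) / period
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * phase))


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def train(model: TissueClassifier, dataset: Sequence[PullbackVideo],
          cfg: TrainConfig, log_every: int | None = None) -> TrainingHistory:
    """Run the full training loop on ``model`` in place.

    Each iteration draws a balanced batch of sequences, augments each
    sequence with one constant affine map, runs forward/backward (loss on
    the final frame's prediction) and takes an Adam step at the scheduled
    learning rate.  Fully seeded via ``cfg.seed``.
    """
    L = cfg.resolved_sequence_length(model.spec.recurrent)
    weights = compute_sampling_weights(dataset, sequence_length=L)
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.base_lr)
    history = TrainingHistory()
    for it in range(cfg.total_iterations):
        lr = cyclic_cosine_lr(it, cfg.base_lr, cfg.scheduler_period)
        batch = draw_batch(dataset, weights, cfg.batch_sequences, rng)
        images = batch.images
        if not cfg.augment.is_identity:
            images = np.stack([augment_sequence(seq, cfg.augment, rng) for seq in images])
        optimizer.zero_grad()
        loss = model.train_step_backward(images, batch.targets,
                                         supervise_all=cfg.supervise_all)
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite loss {loss} at iteration {it}; "
                               "lower the learning rate or check the data")
        optimizer.step(lr)
        history.loss.append(loss)
        history.lr.append(lr)
        if log_every and (it + 1) % log_every == 0:
            recent = history.loss[-log_every:]
            print(f"iter {it + 1:5d}  lr {lr:.2e}  loss {np.mean(recent):.4f}")
    return history
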