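"""Synthetic pullback-video generator.

Emulates the statistical structure of an esophageal pullback recording so
the full pipeline is testable without clinical data:

* five tissue classes traversed in the fixed anatomical order
  St → Tz → B → Ts → Sq, each as one contiguous run;
* run lengths apportioned from configurable class proportions (defaults
  mimic the clinical class imbalance, with Barrett dominant), then jittered
  per video to mimic variable anatomy;
* gradual appearance transitions: near a run boundary the image is an
  alpha-blend of the two adjacent class textures while the hard label stays
  crisp — annotation ambiguity lives in the pixels, not the labels;
* sporadic non-informative frames (blur, bubbles, contrast extremes,
  motion smear), never the last frame of a video.

Each class has a distinct procedural texture (base mucosal hue plus a
class-specific spatial modulation) whose phase drifts over time to mimic
the pullback motion.  Textures are deliberately simple: with zero noise and
zero transition width the classes are linearly separable on raw pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .frames import N_CLASSES, Frame, PullbackVideo

DEGRADATION_KINDS = ("blur", "bubbles", "contrast", "motion")

#: Default class proportions, mirroring the clinical frame counts
#: (St 0.13, Tz 0.15, B 0.47, Ts 0.21, Sq 0.04 — Barrett dominant).
DEFAULT_PROPORTIONS = (0.13, 0.15, 0.47, 0.21, 0.04)


@dataclass
class SyntheticConfig:
    image_size: tuple[int, int] = (32, 32)
    frames_per_video: int = 100
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    transition_width: int = 5
    noninformative_rate: float = 0.035
    noise_sd: float = 0.05
    run_length_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.image_size = tuple(self.image_size)  # type: ignore[assignment]
        self.class_proportions = tuple(float(p) for p in self.class_proportions)  # type: ignore[assignment]
        if len(self.class_proportions) != N_CLASSES:
            raise ValueError(f"need {N_CLASSES} class proportions")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if min(self.class_proportions) < 0:
            raise ValueError("class_proportions must be non-negative")
        if self.transition_width < 0:
            raise ValueError("transition_width must be >= 0")
        if not (0.0 <= self.noninformative_rate < 1.0):
            raise ValueError("noninformative_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# --------------------------------------------------------------------- lengths

def apportion_run_lengths(total: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` frames over classes.

    Every class receives at least one frame (a pullback visits all five
    regions); ties on the fractional remainder break toward the earlier
    class for determinism.
    """
    if total < len(proportions):
        raise ValueError(f"cannot host {len(proportions)} classes in {total} frames")
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    quota = total * p
    lengths = np.floor(quota).astype(int)
    remainder = total - lengths.sum()
    order = np.argsort(-(quota - lengths), kind="stable")
    lengths[order[:remainder]] += 1
    # guarantee one frame per class, stealing from the largest run
    while (lengths == 0).any():
        lengths[np.argmax(lengths)] -= 1
        lengths[np.argmin(lengths)] += 1
    return lengths


# -------------------------------------------------------------------- textures

# per class: base RGB hue and (amplitude, x-frequency, y-frequency) of the
# spatial modulation; hues run from deep gastric red to pale squamous pink
_BASE_COLOR = np.array(
    [
        [0.62, 0.28, 0.24],  # St: gastric mucosa, coarse rugae
        [0.78, 0.42, 0.34],  # Tz: junction zone
        [0.85, 0.55, 0.42],  # B : salmon Barrett segment
        [0.88, 0.68, 0.58],  # Ts: Barrett/squamous transition
        [0.94, 0.81, 0.78],  # Sq: pale smooth squamous lining
    ]
)
_PATTERN = np.array(
    [
        # amp, fx, fy
        [0.12, 0.0, 2.0],  # horizontal rugae bands
        [0.09, 3.0, 3.0],  # diagonal irregularity
        [0.07, 6.0, 6.0],  # fine mottle
        [0.08, 3.0, 0.0],  # vertical streaks
        [0.03, 0.0, 1.5],  # near-featureless
    ]
)


def class_texture(class_index: int, image_size: tuple[int, int], phase: float = 0.0) -> np.ndarray:
    """Pure procedural texture of one tissue class, intensities in [0, 1]."""
    H, W = image_size
    amp, fx, fy = _PATTERN[class_index]
    y, x = np.mgrid[0:H, 0:W]
    wave = np.sin(2 * np.pi * (fx * x / W + fy * y / H) + phase)
    img = _BASE_COLOR[class_index][None, None, :] + amp * wave[:, :, None]
    return np.clip(img, 0.0, 1.0)


# transition-zone classes are junction zones: their appearance is a mixture
# of the two anchor tissues they sit between, with the anchor weight sliding
# across the run.  The weight range stays inside (0.25, 0.75) so each frame
# remains nearest its own class centroid (separability with zero noise).
_MIX_ANCHORS = {1: (0, 2), 3: (2, 4)}  # Tz between St and B; Ts between B and Sq
_MIX_RANGE = (0.65, 0.35)  # first-anchor weight at run start -> run end


def class_appearance(class_index: int, position: float, image_size: tuple[int, int],
                     phases: np.ndarray) -> np.ndarray:
    """Appearance of a class at a within-run position in [0, 1].

    Anchor classes (St, B, Sq) have a fixed texture; junction classes (Tz,
    Ts) interpolate between their neighboring anchors as the endoscope
    moves, so their early frames resemble the previous tissue and their
    late frames the next one.
    """
    if class_index in _MIX_ANCHORS:
        a, b = _MIX_ANCHORS[class_index]
        m0, m1 = _MIX_RANGE
        m = m0 + (m1 - m0) * float(np.clip(position, 0.0, 1.0))
        return m * class_texture(a, image_size, phases[a]) + (1.0 - m) * class_texture(
            b, image_size, phases[b])
    return class_texture(class_index, image_size, phases[class_index])


# ----------------------------------------------------------------- degradation

def _degrade_image(image: np.ndarray, kind: str, rng: np.random.Generator,
                   strength: float | None = None) -> np.ndarray:
    """Apply one non-informative degradation to an image (copy returned)."""
    img = np.asarray(image, dtype=float)
    if kind == "blur":
        sigma = 1.5 if strength is None else strength
        return np.clip(ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0)), 0, 1)
    if kind == "bubbles":
        H, W = img.shape[:2]
        out = img.copy()
        n = int(rng.integers(3, 9))
        y, x = np.mgrid[0:H, 0:W]
        for _ in range(n):
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            r = rng.uniform(max(2.0, H / 16), H / 5)
            mask = np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2 * (r / 2) ** 2)))
            out += 0.45 * mask[:, :, None]
        return np.clip(out, 0, 1)
    if kind == "contrast":
        gain = 2.5 if strength is None else strength
        return np.clip(0.5 + gain * (img - 0.5), 0, 1)
    if kind == "motion":
        size = 7 if strength is None else int(strength)
        if size <= 1:
            return img.copy()
        axis = int(rng.integers(0, 2))
        return np.clip(ndimage.uniform_filter1d(img, size=size, axis=axis, mode="nearest"), 0, 1)
    raise ValueError(f"unknown degradation kind {kind!r}; choose from {DEGRADATION_KINDS}")


def degrade_frame(frame: Frame, kind: str, rng: np.random.Generator,
                  strength: float | None = None) -> Frame:
    """Copy of ``frame`` with one degradation applied and informative=False.

    The tissue label is preserved — degradation spoils usability, not
    anatomy.  ``strength`` overrides the kind-specific default (Gaussian
    sigma for blur, gain for contrast, kernel length for motion); a zero /
    unit strength reduces to the identity for blur and motion.
    """
    degraded = _degrade_image(frame.image, kind, rng, strength)
    return Frame(
        image=degraded,
        label=frame.label,
        informative=False,
        patient_id=frame.patient_id,
        video_id=frame.video_id,
        frame_index=frame.frame_index,
    )


# ------------------------------------------------------------------ generation

def generate_pullback(cfg: SyntheticConfig, patient_id: str,
                      rng: np.random.Generator, video_id: str | None = None) -> PullbackVideo:
    """One synthetic pullback video for one patient.

    Run lengths follow largest-remainder apportionment of
    ``cfg.class_proportions``, jittered by ±``run_length_jitter`` so videos
    differ while preserving the anatomical class order.  Within
    ``transition_width`` frames of a run boundary the image alpha-blends the
    two adjacent class textures (up to 50/50 at the boundary itself); the
    hard label follows the ground-truth boundary exactly.
    """
    T = cfg.frames_per_video
    if T < N_CLASSES:
        raise ValueError(f"frames_per_video={T} cannot host all {N_CLASSES} classes")
    video_id = video_id or f"{patient_id}_v0"
    H, W = cfg.image_size

    base = apportion_run_lengths(T, cfg.class_proportions)
    if cfg.run_length_jitter > 0:
        jitter = rng.uniform(-cfg.run_length_jitter, cfg.run_length_jitter, size=N_CLASSES)
        lengths = apportion_run_lengths(T, base * (1.0 + jitter))
    else:
        lengths = base
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    labels = np.repeat(np.arange(N_CLASSES), lengths)

    phases = rng.uniform(0, 2 * np.pi, size=N_CLASSES)
    drift = rng.uniform(0.1, 0.25)  # pullback motion: texture phase per frame

    # interior boundaries: frame index of the first frame of runs 1..4
    boundaries = starts[1:]
    images = np.empty((T, H, W, 3), dtype=np.float64)
    w = cfg.transition_width
    for t in range(T):
        c = int(labels[t])
        pos = (t - starts[c]) / max(int(lengths[c]) - 1, 1)
        # (class, within-run position, weight) contributions to this frame
        parts: list[tuple[int, float, float]] = [(c, pos, 1.0)]
        if w > 0:
            for b in boundaries:
                dist = abs((t + 0.5) - b)  # distance to the boundary midline
                if dist < w:
                    left, right = int(labels[b - 1]), int(labels[b])
                    # blend toward the neighbor's appearance at its run edge
                    other, edge = (right, 0.0) if t < b else (left, 1.0)
                    alpha = 0.5 * (1.0 - dist / w)
                    parts[0] = (c, pos, parts[0][2] - alpha)
                    parts.append((other, edge, alpha))
        frame_phases = phases + drift * t
        img = np.zeros((H, W, 3))
        for k, p, weight in parts:
            if weight > 0:
                img += weight * class_appearance(k, p, (H, W), frame_phases)
        images[t] = img

    if cfg.noise_sd > 0:
        images += rng.normal(0.0, cfg.noise_sd, size=images.shape)
    images = np.clip(images, 0.0, 1.0)

    informative = np.ones(T, dtype=bool)
    n_bad = int(round(cfg.noninformative_rate * T))
    n_bad = min(n_bad, T - 1)
    if n_bad > 0:
        # never the last frame: training sequences must end informative
        bad = rng.choice(T - 1, size=n_bad, replace=False)
        for t in bad:
            kind = DEGRADATION_KINDS[rng.integers(0, len(DEGRADATION_KINDS))]
            images[t] = _degrade_image(images[t], kind, rng)
            informative[t] = False

    video = PullbackVideo(
        patient_id=patient_id,
        video_id=video_id,
        images=images.astype(np.float32),
        labels=labels,
        informative=informative,
    )
    video.validate()
    return video


def generate_cohort(cfg: SyntheticConfig, n_patients: int,
                    seed: int | None = None) -> list[PullbackVideo]:
    """One video per patient, with per-patient derived seeds.

    The same ``(cfg, seed)`` always reproduces the identical cohort.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    videos = []
    for i, child in enumerate(root.spawn(n_patients)):
        pid = f"P{i:03d}"
        videos.append(generate_pullback(cfg, pid, np.random.default_rng(child)))
    return videos
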