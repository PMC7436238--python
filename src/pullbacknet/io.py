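"""Dataset readers/writers: one directory of PNG frames per video plus a
``labels.csv`` table at the dataset root.

Layout::

    root/
      labels.csv            # patient_id,video_id,frame_index,label,informative
      <video_id>/frame_000000.png
      <video_id>/frame_000001.png
      ...

PNG is lossless, so a write/load round-trip preserves image bytes exactly
(frames are stored as 8-bit RGB).  The CSV is comma-separated with a
mandatory header row, UTF-8, ``label`` in {St,Tz,B,Ts,Sq} and
``informative`` in {0,1}.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .frames import CLASS_TO_INDEX, CLASSES, PullbackVideo

CSV_COLUMNS = ["patient_id", "video_id", "frame_index", "label", "informative"]


def frame_filename(frame_index: int) -> str:
    return f"frame_{frame_index:06d}.png"


def to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)


def save_dataset(videos: Sequence[PullbackVideo], root: str | Path) -> Path:
    """Write a cohort to ``root``; returns the path of labels.csv."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for video in videos:
        vdir = root / video.video_id
        vdir.mkdir(parents=True, exist_ok=True)
        for t in range(len(video)):
            idx = int(video.frame_index[t])
            Image.fromarray(to_uint8(video.images[t])).save(vdir / frame_filename(idx))
            rows.append({
                "patient_id": video.patient_id,
                "video_id": video.video_id,
                "frame_index": idx,
                "label": CLASSES[video.labels[t]],
                "informative": int(video.informative[t]),
            })
    table = pd.DataFrame(rows, columns=CSV_COLUMNS)
    csv_path = root / "labels.csv"
    table.to_csv(csv_path, index=False)
    return csv_path


def load_dataset(root: str | Path) -> list[PullbackVideo]:
    """Load a frame-directory dataset written by :func:`save_dataset`.

    Frames are sorted by frame_index within each video; labels are
    validated against the five-class alphabet, unknown labels are reported
    with their CSV row number, and a missing frame file is an error naming
    the file.
    """
    root = Path(root)
    csv_path = root / "labels.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no labels.csv found in {root}")
    table = pd.read_csv(csv_path, dtype={"patient_id": str, "video_id": str})
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"labels.csv is missing columns {missing}")
    bad = ~table["label"].isin(CLASSES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown label {table['label'].iloc[row]!r} in labels.csv row {row + 2} "
            f"(expected one of {list(CLASSES)})"
        )
    videos = []
    for (pid, vid), group in table.groupby(["patient_id", "video_id"], sort=True):
        group = group.sort_values("frame_index")
        images = []
        for idx in group["frame_index"]:
            path = root / str(vid) / frame_filename(int(idx))
            if not path.exists():
                raise FileNotFoundError(f"frame file missing: {path}")
            with Image.open(path) as im:
                images.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
        videos.append(PullbackVideo(
            patient_id=str(pid),
            video_id=str(vid),
            images=np.stack(images),
            labels=[CLASS_TO_INDEX[l] for l in group["label"]],
            informative=group["informative"].to_numpy().astype(bool),
            frame_index=group["frame_index"].to_numpy(),
        ))
    if not videos:
        raise ValueError(f"dataset at {root} contains no videos")
    return videos


@dataclass
class DatasetManifest:
    """Lightweight inventory of a frame-directory dataset."""

    root: str
    videos: list[dict]
    labels_csv_sha256: str

    @property
    def n_frames(self) -> int:
        return sum(v["frame_count"] for v in self.videos)


def build_manifest(root: str | Path) -> DatasetManifest:
    """Summarize and verify a dataset directory.

    Confirms that every referenced frame file exists and that each frame is
    labeled exactly once; records per-video frame counts and label
    histograms plus a checksum of labels.csv.
    """
    root = Path(root)
    csv_path = root / "labels.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no labels.csv found in {root}")
    digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    table = pd.read_csv(csv_path, dtype={"patient_id": str, "video_id": str})
    dup = table.duplicated(subset=["video_id", "frame_index"])
    if dup.any():
        raise ValueError("labels.csv labels some frame more than once")
    entries = []
    for (pid, vid), group in table.groupby(["patient_id", "video_id"], sort=True):
        for idx in group["frame_index"]:
            path = root / str(vid) / frame_filename(int(idx))
            if not path.exists():
                raise FileNotFoundError(f"frame file missing: {path}")
        hist = {c: int((group["label"] == c).sum()) for c in CLASSES}
        entries.append({
            "patient_id": str(pid),
            "video_id": str(vid),
            "frame_count": int(len(group)),
            "label_histogram": hist,
        })
    return DatasetManifest(root=str(root), videos=entries, labels_csv_sha256=digest)
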