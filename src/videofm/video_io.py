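"""Video input: frame loading, manual frame exclusion, contiguous segments.

Maternal-movement frames are removed *manually* upstream; this module only
honors an exclusion list (JSON: a list of frame numbers and/or ``[start,
end)`` pairs).  All downstream signal analysis runs per contiguous segment —
signals are never concatenated across exclusion gaps, since a seam between
non-adjacent frames would register as a large spurious motion spike.

Frame indexing is 0-based throughout; segments are half-open ``[start, end)``
intervals of *original* frame numbers.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSequence",
    "Segment",
    "load_video",
    "load_exclusions",
    "contiguous_segments",
]


@dataclass
class FrameSequence:
    """Ordered RGB frames with time bookkeeping.

    Attributes
    ----------
    frames : list of ndarray
        RGB uint8 images, all of identical height/width.
    fps : float
        Frame rate in Hz (must be > 0).
    frame_indices : ndarray of int
        Original 0-based frame numbers, strictly increasing; never contains
        an excluded frame.
    excluded : frozenset of int
        Original frame numbers removed before analysis.
    """

    frames: list[np.ndarray]
    fps: float
    frame_indices: np.ndarray
    excluded: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if len(self.frames) != len(self.frame_indices):
            raise ValueError("frames and frame_indices length mismatch")
        if len(self.frames) > 0:
            shape0 = self.frames[0].shape[:2]
            if any(f.shape[:2] != shape0 for f in self.frames):
                raise ValueError("all frames must share the same height/width")
            if np.any(np.diff(self.frame_indices) <= 0):
                raise ValueError("frame_indices must be strictly increasing")
        if self.excluded.intersection(self.frame_indices.tolist()):
            raise ValueError("excluded frames present in frame_indices")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        """Total analyzed time (number of retained frames / fps)."""
        return len(self.frames) / self.fps


@dataclass(frozen=True)
class Segment:
    """Maximal run of consecutive retained frames, half-open ``[start, end)``."""

    start_index: int
    end_index: int
    fps: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("segment must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.end_index - self.start_index

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def _normalize_exclusions(exclusions: Iterable) -> frozenset[int]:
    out: set[int] = set()
    for item in exclusions:
        if isinstance(item, (list, tuple)):
            start, end = item
            out.update(range(int(start), int(end)))
        else:
            out.add(int(item))
    return frozenset(out)


def load_exclusions(path: str | os.PathLike) -> frozenset[int]:
    """Read an exclusion file: JSON list of frame numbers or [start, end) pairs."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError("exclusion file must contain a JSON list")
    return _normalize_exclusions(data)


def _read_frames(path: Path) -> tuple[list[np.ndarray], float | None]:
    """Decode frames from a video file or a lossless image-stack directory.

    An image-stack directory contains numbered still images (PNG/TIFF/...)
    in lexicographic frame order, optionally with a ``meta.json`` carrying
    ``{"fps": <float>}``.
    """
    if path.is_dir():
        stems = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}
        )
        if not stems:
            raise ValueError(f"no image frames found in directory {path}")
        frames = [np.asarray(iio.imread(p)) for p in stems]
        fps = None
        meta = path / "meta.json"
        if meta.exists():
            with open(meta) as fh:
                fps = json.load(fh).get("fps")
        return frames, fps
    # Single container file (e.g. an animated format imageio can decode).
    try:
        arr = iio.imread(path, index=None)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable container
        raise OSError(f"could not decode video file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[None]  # single still image
    frames = [np.ascontiguousarray(f) for f in arr]
    fps = None
    try:
        meta = iio.immeta(path)
        fps = meta.get("fps")
    except Exception:
        pass
    return frames, fps


def load_video(
    path: str | os.PathLike,
    exclusions: Iterable | None = None,
    fps: float | None = None,
) -> FrameSequence:
    """Load a video (file or image-stack directory) into a :class:`FrameSequence`.

    Parameters
    ----------
    path : path
        Video file decodable by imageio, or a directory of numbered frames.
    exclusions : iterable, optional
        Frame numbers (ints) and/or ``[start, end)`` pairs to drop.
    fps : float, optional
        Overrides the frame rate from container metadata.  When both are
        present and disagree, the explicit value wins with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames, meta_fps = _read_frames(path)
    if len(frames) == 0:
        raise ValueError(f"no decodable frames in {path}")

    excluded = _normalize_exclusions(exclusions or ())
    n = len(frames)
    bad = [e for e in excluded if not (0 <= e < n)]
    if bad:
        raise ValueError(f"exclusions out of range [0, {n}): {sorted(bad)[:5]}")

    if fps is not None and meta_fps is not None and abs(fps - meta_fps) > 1e-9:
        logger.warning(
            "fps override %s differs from container metadata %s; using override",
            fps, meta_fps,
        )
    effective_fps = fps if fps is not None else meta_fps
    if effective_fps is None:
        effective_fps = 25.0
        logger.warning("no fps in metadata or config; assuming %s fps", effective_fps)

    keep = [i for i in range(n) if i not in excluded]
    rgb = []
    for i in keep:
        f = frames[i]
        if f.ndim == 2:
            f = np.stack([f] * 3, axis=-1)
        if f.shape[-1] == 4:
            f = f[..., :3]
        rgb.append(np.ascontiguousarray(f.astype(np.uint8, copy=False)))
    return FrameSequence(
        frames=rgb,
        fps=float(effective_fps),
        frame_indices=np.asarray(keep, dtype=np.int64),
        excluded=excluded,
    )


def contiguous_segments(seq: FrameSequence, min_len_s: float = 0.0) -> list[Segment]:
    """Split retained frames into maximal runs of consecutive original indices.

    Runs shorter than ``min_len_s`` seconds are dropped.  Returned segments
    are ordered and non-overlapping; the list may be empty.
    """
    if len(seq) == 0:
        raise ValueError("empty frame sequence")
    idx = seq.frame_indices
    breaks = np.flatnonzero(np.diff(idx) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    segments = []
    for s, e in zip(starts, ends):
        seg = Segment(int(idx[s]), int(idx[e]) + 1, seq.fps)
        if seg.duration_s >= min_len_s:
            segments.append(seg)
    return segments


def segment_positions(seq: FrameSequence, segment: Segment) -> np.ndarray:
    """Positions (into ``seq.frames``) of the frames belonging to ``segment``."""
    mask = (seq.frame_indices >= segment.start_index) & (
        seq.frame_indices < segment.end_index
    )
    return np.flatnonzero(mask)
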