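"""Dense optical flow → hue/saturation motion coding → H and S time series.

Between each consecutive frame pair the per-pixel displacement field is
estimated with a deterministic iterative Lucas–Kanade solver.  Each motion
vector is then coded in HSL: hue carries the direction, saturation the
magnitude (stationary pixels render white — saturation 0).  Averaging the H
and S planes over the abdominal mask (one scalar per frame pair) yields the
two motion time series sampled at the video frame rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.registration import optical_flow_ilk

from videofm.abdomen_detect import RegionMask

logger = logging.getLogger(__name__)

__all__ = [
    "FlowParams",
    "FlowField",
    "HSTimeSeries",
    "dense_flow",
    "encode_hs",
    "region_average",
    "build_series",
]


@dataclass(frozen=True)
class FlowParams:
    """Settings of the dense flow solver (all deterministic)."""

    radius: int = 7        # local window radius, px
    num_warp: int = 2      # coarse-to-fine warp iterations
    gaussian: bool = False
    prefilter: bool = False
    m_norm: float = 5.0    # saturation normalization, px/frame


@dataclass
class FlowField:
    """Per-pixel displacement for a frame pair (k, k+1).

    ``u`` is the horizontal component (+right), ``v`` the vertical component
    (+down, image coordinates), both in pixels/frame.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class HSTimeSeries:
    """Region-averaged hue and saturation motion signals for one segment.

    One sample per consecutive frame pair; ``k_indices`` are the pair indices
    (index of the earlier frame within the segment) actually produced —
    pairs whose abdominal mask was empty are dropped.
    """

    H: np.ndarray
    S: np.ndarray
    fs: float
    segment_id: int = 0
    k_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.H.shape != self.S.shape:
            raise ValueError("H and S must have the same length")
        if self.k_indices is None:
            self.k_indices = np.arange(len(self.H))
        self.k_indices = np.asarray(self.k_indices, dtype=np.int64)
        if len(self.k_indices) != len(self.H):
            raise ValueError("k_indices length mismatch")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    def __len__(self) -> int:
        return len(self.H)

    @property
    def t_seconds(self) -> np.ndarray:
        return self.k_indices / self.fs


def dense_flow(
    frame_k: np.ndarray, frame_k1: np.ndarray, params: FlowParams | None = None
) -> FlowField:
    """Dense displacement field from ``frame_k`` to ``frame_k1``."""
    params = params or FlowParams()
    if frame_k.shape != frame_k1.shape:
        raise ValueError("frame shapes differ")
    g0 = rgb2gray(frame_k) if frame_k.ndim == 3 else frame_k.astype(np.float64)
    g1 = rgb2gray(frame_k1) if frame_k1.ndim == 3 else frame_k1.astype(np.float64)
    # The solver registers the second image onto the first: the returned
    # (row, col) field is the forward motion of scene content from k to k+1.
    flow = optical_flow_ilk(
        g0,
        g1,
        radius=params.radius,
        num_warp=params.num_warp,
        gaussian=params.gaussian,
        prefilter=params.prefilter,
    )
    return FlowField(u=flow[1], v=flow[0])


def encode_hs(flow: FlowField, m_norm: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """HSL coding of a flow field: hue = direction, saturation = magnitude.

    Hue is the vector angle in degrees in [0, 360), counterclockwise from +u
    with v pointing down (image coordinates), so (0, +m) maps to 270°.
    Saturation is ``min(|flow| / m_norm, 1)``; a zero vector gets hue 0 and
    saturation 0 (renders white).
    """
    if m_norm <= 0:
        raise ValueError("m_norm must be > 0")
    mag = flow.magnitude
    hue = np.degrees(np.arctan2(-flow.v, flow.u)) % 360.0
    hue[mag == 0] = 0.0
    sat = np.minimum(mag / m_norm, 1.0)
    return hue, sat


def region_average(channel: np.ndarray, mask: RegionMask) -> float:
    """Arithmetic mean of a channel over the abdominal pixels.

    Raises on an empty mask; the caller drops the sample instead.
    """
    if mask.empty:
        raise ValueError("empty mask: no pixels to average")
    return float(np.asarray(channel, dtype=np.float64)[mask.mask].mean())


def build_series(
    frames: list[np.ndarray],
    masks: list[RegionMask],
    fps: float,
    params: FlowParams | None = None,
    segment_id: int = 0,
    max_missing_frac: float = 0.10,
) -> HSTimeSeries | None:
    """H and S series for one contiguous segment.

    For each consecutive frame pair: dense flow → HS coding → average over
    the mask of the *earlier* frame.  Pairs with an empty mask are dropped;
    if more than ``max_missing_frac`` of the pairs are missing the whole
    segment is rejected (returns ``None`` with a warning).
    """
    params = params or FlowParams()
    if len(frames) != len(masks):
        raise ValueError("frames and masks length mismatch")
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to build a series")
    hs, ss, ks = [], [], []
    n_pairs = len(frames) - 1
    for k in range(n_pairs):
        if masks[k].empty:
            logger.info("segment %d: empty mask at pair %d, sample dropped",
                        segment_id, k)
            continue
        flow = dense_flow(frames[k], frames[k + 1], params)
        hue, sat = encode_hs(flow, params.m_norm)
        hs.append(region_average(hue, masks[k]))
        ss.append(region_average(sat, masks[k]))
        ks.append(k)
    missing = n_pairs - len(ks)
    if missing > max_missing_frac * n_pairs:
        logger.warning(
            "segment %d rejected: %d/%d samples missing", segment_id, missing, n_pairs
        )
        return None
    return HSTimeSeries(
        H=np.asarray(hs), S=np.asarray(ss), fs=fps,
        segment_id=segment_id, k_indices=np.asarray(ks, dtype=np.int64),
    )
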