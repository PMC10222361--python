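"""Maternal abdominal region detection.

Per frame: (1) classify skin pixels with an elliptical boundary model in
YCbCr chroma space, (2) clean the binary mask with a morphological opening,
(3) label 8-connected components and keep the candidates whose bounding-box
aspect ratio (width / height) exceeds 1 — a supine subject's abdomen is
wider than tall — returning the largest such component.

The default ellipse follows the classical elliptical skin-chroma boundary
(center, semi-axes and tilt fitted to skin tones in the Cb–Cr plane).  Skin
chroma is lighting-dependent, so every parameter is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening

__all__ = [
    "SkinModel",
    "RegionMask",
    "rgb_to_cbcr",
    "skin_mask",
    "open_mask",
    "select_abdomen",
    "detect_abdomen",
]

# Reference frame width at which `opening_radius_px` is specified; the
# radius scales proportionally for other widths.
REFERENCE_FRAME_WIDTH = 1280


@dataclass(frozen=True)
class SkinModel:
    """Elliptical skin boundary in the Cb–Cr chroma plane.

    A pixel with chroma ``(Cb, Cr)`` is skin iff the point, shifted to the
    ellipse center and rotated by ``-theta``, satisfies
    ``(x/a)**2 + (y/b)**2 <= 1``.
    """

    cx: float = 109.38   # ellipse center, Cb axis
    cy: float = 152.02   # ellipse center, Cr axis
    a: float = 25.39     # semi-axis along the rotated major direction
    b: float = 14.03     # semi-axis along the rotated minor direction
    theta: float = 2.53  # tilt of the major axis, radians (CCW from +Cb)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
        """Vectorized ellipse membership test on chroma coordinates."""
        dx = np.asarray(cb, dtype=np.float64) - self.cx
        dy = np.asarray(cr, dtype=np.float64) - self.cy
        c, s = np.cos(self.theta), np.sin(self.theta)
        x = c * dx + s * dy
        y = -s * dx + c * dy
        return (x / self.a) ** 2 + (y / self.b) ** 2 <= 1.0

    def center_rgb(self, y_luma: float = 150.0) -> tuple[int, int, int]:
        """An RGB color whose chroma sits exactly at the ellipse center.

        Useful for rendering synthetic skin guaranteed to pass the test.
        """
        r = y_luma + 1.402 * (self.cy - 128.0)
        g = y_luma - 0.344136 * (self.cx - 128.0) - 0.714136 * (self.cy - 128.0)
        b = y_luma + 1.772 * (self.cx - 128.0)
        return tuple(int(round(np.clip(v, 0, 255))) for v in (r, g, b))


@dataclass
class RegionMask:
    """Boolean region mask with provenance through the detection stages."""

    mask: np.ndarray
    stage: str  # one of {"skin", "opened", "selected"}
    empty: bool = field(init=False)
    area_px: int = field(init=False)
    bbox: tuple[int, int, int, int] | None = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.stage not in ("skin", "opened", "selected"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.area_px = int(self.mask.sum())
        self.empty = self.area_px == 0
        if self.empty:
            self.bbox = None
        else:
            rows = np.flatnonzero(self.mask.any(axis=1))
            cols = np.flatnonzero(self.mask.any(axis=0))
            self.bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def rgb_to_cbcr(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cb and Cr chroma planes (BT.601, full range, offset 128) of an RGB frame."""
    f = np.asarray(frame, dtype=np.float64)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return cb, cr


def skin_mask(frame: np.ndarray, model: SkinModel | None = None) -> RegionMask:
    """Per-pixel skin classification of an RGB uint8 frame."""
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("frame must be an RGB image (H, W, 3)")
    model = model or SkinModel()
    cb, cr = rgb_to_cbcr(frame)
    return RegionMask(model.contains(cb, cr), stage="skin")


def open_mask(mask: RegionMask, radius_px: int = 5) -> RegionMask:
    """Morphological opening (erosion then dilation) with a disk element."""
    if radius_px < 1:
        raise ValueError("opening radius must be >= 1 px")
    opened = opening(mask.mask, footprint=disk(radius_px))
    return RegionMask(opened, stage="opened")


def select_abdomen(mask: RegionMask) -> RegionMask:
    """Pick the abdominal component from an opened skin mask.

    Components are labeled with 8-connectivity; candidates are those whose
    bounding-box width/height ratio exceeds 1; the largest-area candidate
    wins.  If nothing qualifies an empty-flagged mask is returned and the
    frame is skipped downstream.
    """
    if mask.stage != "opened":
        raise ValueError("select_abdomen expects a mask at stage 'opened'")
    out = np.zeros_like(mask.mask)
    if mask.empty:
        return RegionMask(out, stage="selected")
    labeled = label(mask.mask, connectivity=2)
    best_area = 0
    best_label = 0
    for region in regionprops(labeled):
        r0, c0, r1, c1 = region.bbox
        width, height = c1 - c0, r1 - r0
        if width / height > 1.0 and region.area > best_area:
            best_area = region.area
            best_label = region.label
    if best_label:
        out = labeled == best_label
    return RegionMask(out, stage="selected")


def detect_abdomen(
    frame: np.ndarray,
    model: SkinModel | None = None,
    opening_radius_px: int = 5,
    scale_radius: bool = True,
) -> RegionMask:
    """Full single-frame abdomen detection: skin → opened → selected.

    ``opening_radius_px`` is specified at the 1280-px reference frame width
    and scaled proportionally (minimum 1 px) when ``scale_radius`` is on.
    """
    radius = opening_radius_px
    if scale_radius:
        radius = max(1, round(opening_radius_px * frame.shape[1] / REFERENCE_FRAME_WIDTH))
    return select_abdomen(open_mask(skin_mask(frame, model), radius))
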