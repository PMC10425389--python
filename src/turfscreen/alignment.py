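"""Integer-pixel band-to-band registration (RED aligned onto the NIR frame).

The multispectral lenses sit at slightly different physical positions, so band
images are captured a few pixels apart.  The analysis registers RED onto NIR
either from camera metadata (the relative optical center of each lens) or by an
exhaustive integer-shift search.  Shifts are integer-only — pixel DN values are
never resampled — and the border exposed by a shift is marked invalid (NaN) so
it can be excluded from histograms and ROI means downstream.

A :class:`PixelOffset` always means "the shift to apply to the moving (RED)
raster so its content lands on the reference (NIR) frame"; dy > 0 moves content
down, dx > 0 moves it right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PixelOffset:
    dy: int
    dx: int

    def __post_init__(self) -> None:
        if self.dy != int(self.dy) or self.dx != int(self.dx):
            raise InvalidParameterError("pixel offsets must be integers")

    def __neg__(self) -> "PixelOffset":
        return PixelOffset(-self.dy, -self.dx)


@dataclass(frozen=True)
class BandMeta:
    """Lens metadata: optical center position relative to the NIR lens (px)."""

    band: str
    center_x: float
    center_y: float


def offset_from_metadata(red_meta: BandMeta | None,
                         nir_meta: BandMeta | None) -> PixelOffset | None:
    """Corrective shift for RED from relative-optical-center metadata.

    Returns ``(nir.y - red.y, nir.x - red.x)`` rounded to integers, or ``None``
    when metadata is missing (callers fall back to :func:`estimate_offset`).
    """
    if red_meta is None or nir_meta is None:
        logger.warning("band metadata missing; falling back to offset estimation")
        return None
    dy = int(round(nir_meta.center_y - red_meta.center_y))
    dx = int(round(nir_meta.center_x - red_meta.center_x))
    return PixelOffset(dy, dx)


def shift_band(raster: np.ndarray, offset: PixelOffset) -> np.ndarray:
    """Translate raster content by ``offset``; exposed border becomes NaN.

    ``shift_band(shift_band(x, o), -o)`` restores the interior of ``x``
    exactly.  Output is float so the invalid border can be encoded as NaN.
    """
    h, w = raster.shape
    dy, dx = offset.dy, offset.dx
    if abs(dy) >= h or abs(dx) >= w:
        raise GeometryError(
            f"offset ({dy}, {dx}) exceeds raster extent {raster.shape}"
        )
    out = np.full((h, w), np.nan, dtype=float)
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = raster[src_r, src_c]
    return out


def gradient_magnitude(raster: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, NaN-safe (NaNs treated as local mean).

    Band images of vegetation can be anti-correlated in raw intensity (RED is
    dark where NIR is bright), which defeats an intensity-difference criterion;
    their *edges* coincide, so inter-band offset search runs on this map.
    """
    r = np.asarray(raster, dtype=float)
    bad = ~np.isfinite(r)
    if bad.any():
        r = np.where(bad, np.nanmean(r), r)
    gy = ndimage.sobel(r, axis=0)
    gx = ndimage.sobel(r, axis=1)
    return np.hypot(gy, gx)


def estimate_offset(reference: np.ndarray, moving: np.ndarray, max_shift: int = 10,
                    on_gradient: bool = False) -> PixelOffset:
    """Exhaustive integer-shift search minimizing mean squared difference.

    Scores every (dy, dx) within ±``max_shift`` by the sum of squared
    differences between ``reference`` and the shifted ``moving`` raster over
    their finite overlap, normalized by overlap area.  Ties break toward the
    smallest |dy|+|dx|, then smallest dy, then dx.  With ``on_gradient`` the
    search runs on Sobel gradient magnitudes (use for cross-band registration).
    """
    if reference.shape != moving.shape:
        raise GeometryError("reference and moving rasters must share a shape")
    if max_shift < 0:
        raise InvalidParameterError("max_shift must be >= 0")
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if on_gradient:
        ref = gradient_magnitude(ref)
        mov = gradient_magnitude(mov)

    best: tuple[float, int, int, int] | None = None
    best_offset: PixelOffset | None = None
    h, w = ref.shape
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            src_r = slice(max(0, -dy), min(h, h - dy))
            src_c = slice(max(0, -dx), min(w, w - dx))
            dst_r = slice(max(0, dy), min(h, h + dy))
            dst_c = slice(max(0, dx), min(w, w + dx))
            a = ref[dst_r, dst_c]
            b = mov[src_r, src_c]
            valid = np.isfinite(a) & np.isfinite(b)
            n = int(valid.sum())
            if n == 0:
                continue  # empty overlap: shift excluded
            d = a[valid] - b[valid]
            score = float(d @ d) / n
            key = (score, abs(dy) + abs(dx), dy, dx)
            if best is None or key < best:
                best = key
                best_offset = PixelOffset(dy, dx)
    if best_offset is None:
        raise GeometryError("no shift with nonempty overlap within max_shift")
    return best_offset
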