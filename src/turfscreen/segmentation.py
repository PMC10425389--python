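"""Dual-mask canopy/green segmentation: NIR + Otsu and ExG + Otsu.

The total canopy (green plus browned foliage) is separated from soil on the
NIR reflectance raster, where live and senescent tissue both sit well above
the flat soil background.  The green-only area is separated on the Excess
Green index of the (calibrated, equalized) RGB composite.  Both scalar rasters
are binarized by Otsu's method; foreground ("white") is grass / green area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ConfigError, DegenerateInputError

OTSU_BINS = 256


@dataclass
class BinaryMask:
    """Boolean raster; True = grass / green foreground. Invalid source pixels
    are always background."""

    mask: np.ndarray
    provenance: Literal["nir-canopy", "exg-green"]
    threshold: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


def excess_green(rgb: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Excess Green index, ``2g − r − b``.

    In the default normalized mode the channels are first divided by their sum
    (chromaticity coordinates), which makes the index invariant to
    multiplicative illumination changes and bounds it in [−1, 2]; pixels with
    zero channel sum are invalid (NaN).  The raw variant computes
    ``2G − R − B`` on the channel values directly.
    """
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ConfigError(f"expected an (H, W, 3) image, got shape {img.shape}")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    if not normalized:
        return 2.0 * g - r - b
    total = r + g + b
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = (2.0 * g - r - b) / total
    exg[~(total > 0)] = np.nan
    return exg


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold on a 256-bin histogram of the finite values.

    Candidate cuts are the histogram bin boundaries; the returned threshold
    maximizes the between-class variance ω₀ω₁(μ₀−μ₁)², with ties resolved to
    the lowest cut.  Classification convention everywhere in this package:
    foreground = value **strictly greater** than the threshold.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DegenerateInputError("no finite values to threshold")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateInputError("all values identical; no threshold exists")
    counts, edges = np.histogram(v, bins=OTSU_BINS, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])

    n = counts.sum()
    w0 = np.cumsum(counts)[:-1]  # pixels in bins <= cut k, k = 0..bins-2
    w1 = n - w0
    csum = np.cumsum(counts * centers)[:-1]
    total = float((counts * centers).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        between = w0.astype(float) * w1.astype(float) * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    k = int(np.argmax(between))  # argmax takes the first (lowest) tied cut
    return float(edges[k + 1])


def _binarize(raster: np.ndarray, provenance) -> BinaryMask:
    r = np.asarray(raster, dtype=float)
    t = otsu_threshold(r)
    mask = np.zeros(r.shape, dtype=bool)
    finite = np.isfinite(r)
    mask[finite] = r[finite] > t
    return BinaryMask(mask=mask, provenance=provenance, threshold=t)


def make_masks(nir_reflectance: np.ndarray,
               equalized_rgb: np.ndarray,
               normalized_exg: bool = True) -> tuple[BinaryMask, BinaryMask]:
    """Canopy mask from NIR, green mask from ExG of the equalized RGB image.

    The two masks are deliberately independent (the green mask is not clipped
    to the canopy): green-tinted ground confounders can push a region's green
    count above its canopy count, which the downstream cover-percentage cap
    absorbs.
    """
    nir = np.asarray(nir_reflectance, dtype=float)
    if nir.shape != np.asarray(equalized_rgb).shape[:2]:
        raise ConfigError("NIR raster and RGB image shapes differ")
    canopy = _binarize(nir, "nir-canopy")
    exg = excess_green(equalized_rgb, normalized=normalized_exg)
    green = _binarize(exg, "exg-green")
    return canopy, green
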