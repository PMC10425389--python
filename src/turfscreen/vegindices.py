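"""Vegetation indices on calibrated reflectance, summarized over canopy ROIs.

    NDVI = (NIR − RED) / (NIR + RED)
    NDRE = (NIR − RedEdge) / (NIR + RedEdge)
    SAVI = ((NIR − RED) / (NIR + RED + L)) · (1 + L),        L = 0.5
    EVI  = G · (NIR − RED) / (NIR + C1·RED − C2·BLUE + L),   G = 2.5, C1 = 6,
                                                             C2 = 7.5, L = 1

All inputs are surface reflectance in [0, 1].  Pixels with a zero or — for
EVI — nonpositive denominator are marked missing (NaN) rather than clamped,
so they cannot bias ROI means.  Per-replicate summaries average the index
over pixels that are canopy foreground and finite, excluding the soil
background exactly as the cover measurement does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .greencover import ROISet
from .segmentation import BinaryMask

logger = logging.getLogger(__name__)

INDEX_IDS = ("ndvi", "ndre", "savi", "evi")

#: bands each index consumes (RED is expected NIR-registered upstream)
REQUIRED_BANDS = {
    "ndvi": ("nir", "red"),
    "ndre": ("nir", "rededge"),
    "savi": ("nir", "red"),
    "evi": ("nir", "red", "blue"),
}


@dataclass(frozen=True)
class VIParams:
    savi_l: float = 0.5
    evi_g: float = 2.5
    evi_c1: float = 6.0
    evi_c2: float = 7.5
    evi_l: float = 1.0


@dataclass
class ViRecord:
    germplasm: str
    session: int
    replicate: int
    index: str
    value: float  # mean over contributing grass pixels, NaN when none
    n_pixels: int

    @property
    def valid(self) -> bool:
        return math.isfinite(self.value)


def compute_vi(bands: dict[str, np.ndarray], index: str,
               params: VIParams = VIParams()) -> np.ndarray:
    """Per-pixel vegetation index raster (float, NaN = missing)."""
    if index not in INDEX_IDS:
        raise ConfigError(f"unknown vegetation index {index!r}")
    missing = [b for b in REQUIRED_BANDS[index] if b not in bands]
    if missing:
        raise ConfigError(f"{index} requires bands {missing} which are absent")
    b = {k: np.asarray(v, dtype=float) for k, v in bands.items()}
    nir = b["nir"]

    with np.errstate(divide="ignore", invalid="ignore"):
        if index == "ndvi":
            den = nir + b["red"]
            vi = (nir - b["red"]) / den
            vi[den == 0] = np.nan
        elif index == "ndre":
            den = nir + b["rededge"]
            vi = (nir - b["rededge"]) / den
            vi[den == 0] = np.nan
        elif index == "savi":
            den = nir + b["red"] + params.savi_l
            vi = (nir - b["red"]) / den * (1.0 + params.savi_l)
            vi[den == 0] = np.nan
        else:  # evi
            den = nir + params.evi_c1 * b["red"] - params.evi_c2 * b["blue"] + params.evi_l
            vi = params.evi_g * (nir - b["red"]) / den
            vi[den <= 0] = np.nan
    return vi


def roi_masked_mean(vi: np.ndarray, canopy: BinaryMask, rois: ROISet,
                    index: str = "", germplasm: str = "",
                    session: int = 0) -> list[ViRecord]:
    """Mean index over grass pixels per replicate ROI, background excluded."""
    vi = np.asarray(vi, dtype=float)
    if vi.shape != canopy.shape:
        raise ConfigError("index raster and canopy mask shapes differ")
    records = []
    for replicate, roi in enumerate(rois):
        roi.require_within(vi.shape, "ROI")
        sl = roi.slices()
        patch = vi[sl]
        contributing = canopy.mask[sl] & np.isfinite(patch)
        n = int(contributing.sum())
        if n == 0:
            logger.warning(
                "no contributing pixels for %s in %s session %s replicate %s",
                index, germplasm, session, replicate,
            )
            value = float("nan")
        else:
            value = float(patch[contributing].mean())
        records.append(
            ViRecord(germplasm=germplasm, session=session, replicate=replicate,
                     index=index, value=value, n_pixels=n)
        )
    return records
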