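"""Replicate ROI placement and green cover percentage (GCP).

Four rectangular regions of interest are placed inside each germplasm cell;
each ROI is one statistical replicate.  Per ROI,

    GCP (%) = (green cover area) / (total canopy area) × 100,

counting mask foreground pixels inside the ROI.  Values above 100% — which
arise when a green-tinted ground confounder inflates the green mask beyond the
canopy mask — are normalized to 100% at record creation; the raw value is kept
alongside for audit.  A replicate with zero canopy pixels has no defined GCP
and is recorded as missing rather than 0 or 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .geometry import Rect
from .segmentation import BinaryMask

logger = logging.getLogger(__name__)

#: ROI footprint from the study protocol, 48.5 × 132 px; the half pixel is not
#: realizable on an integer grid and is floored to 48.
DEFAULT_ROI_SHAPE = (48, 132)
DEFAULT_ROI_COUNT = 4


@dataclass(frozen=True)
class ROISet:
    """The replicate ROIs of one germplasm cell, replicate index = list order."""

    rois: tuple[Rect, ...]

    def __post_init__(self) -> None:
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1:]:
                if a.intersects(b):
                    raise GeometryError(f"ROIs {a} and {b} overlap")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class GcpRecord:
    germplasm: str
    session: int
    replicate: int
    canopy_px: int
    green_px: int
    gcp_raw: float  # uncapped ratio, NaN when canopy_px == 0
    gcp: float  # normalized to [0, 100], NaN when undefined

    @property
    def valid(self) -> bool:
        return math.isfinite(self.gcp)


def place_rois(cell_box: Rect, roi_shape: tuple[int, int] = DEFAULT_ROI_SHAPE,
               n: int = DEFAULT_ROI_COUNT,
               explicit: Sequence[Rect] | None = None) -> ROISet:
    """Deterministically tile ``n`` ROIs in a vertical sequence in the cell box.

    ROIs are evenly spaced top-to-bottom and centered horizontally; explicit
    per-ROI rectangles from configuration override the placement entirely.
    """
    if explicit is not None:
        for r in explicit:
            if not (
                r.row0 >= cell_box.row0 and r.col0 >= cell_box.col0
                and r.row1 <= cell_box.row1 and r.col1 <= cell_box.col1
            ):
                raise GeometryError(f"explicit ROI {r} outside cell box {cell_box}")
        return ROISet(tuple(explicit))
    rh, rw = roi_shape
    if n < 1 or rh < 1 or rw < 1:
        raise GeometryError("need n >= 1 ROIs of positive extent")
    if rw > cell_box.width or n * rh > cell_box.height:
        raise GeometryError(
            f"{n} ROIs of {rh}x{rw} px need {n * rh}x{rw} px, but the cell box "
            f"offers {cell_box.height}x{cell_box.width}"
        )
    slack = cell_box.height - n * rh
    col0 = cell_box.col0 + (cell_box.width - rw) // 2
    rois = []
    for i in range(n):
        # even spacing: slack split into n+1 gaps, rounded to the pixel grid
        gap = round(slack * (i + 1) / (n + 1))
        rois.append(Rect(cell_box.row0 + gap + i * rh, col0, rh, rw))
    return ROISet(tuple(rois))


def green_cover_percent(canopy: BinaryMask, green: BinaryMask, rois: ROISet,
                        germplasm: str = "", session: int = 0) -> list[GcpRecord]:
    """Per-replicate GCP records for one cell."""
    if canopy.shape != green.shape:
        raise GeometryError("canopy and green masks must share a shape")
    records = []
    for replicate, roi in enumerate(rois):
        roi.require_within(canopy.shape, "ROI")
        sl = roi.slices()
        canopy_px = int(canopy.mask[sl].sum())
        green_px = int(green.mask[sl].sum())
        if canopy_px == 0:
            logger.warning(
                "undefined GCP (no canopy pixels) for %s session %s replicate %s",
                germplasm, session, replicate,
            )
            raw = cap = float("nan")
        else:
            raw = 100.0 * green_px / canopy_px
            cap = min(raw, 100.0)
        records.append(
            GcpRecord(
                germplasm=germplasm,
                session=session,
                replicate=replicate,
                canopy_px=canopy_px,
                green_px=green_px,
                gcp_raw=raw,
                gcp=cap,
            )
        )
    return records


def summarize_gcp(records: Sequence[GcpRecord]) -> tuple[float, float]:
    """Mean ± sd of the defined replicate GCPs (NaN, NaN when none defined)."""
    vals = np.array([r.gcp for r in records if r.valid], dtype=float)
    if vals.size == 0:
        return float("nan"), float("nan")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd
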