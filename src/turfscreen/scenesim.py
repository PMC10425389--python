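"""Synthetic multispectral/RGB turf scenes with known ground truth.

The generator emulates nadir frames of a turfgrass screening trial: a germplasm
cell densely covered by canopy (a mixture of green and senescent foliage) on a
spectrally flat sandy soil, with a set of uniform-reflectance calibration tarp
panels in frame.  Per-pixel surface reflectance is painted from class spectral
profiles and pushed through a forward camera model — linear DN response for the
five multispectral bands, exponential DN = a·exp(b·R) for the RGB channels —
with additive Gaussian DN noise and integer quantization.  The RED band content
is translated by an integer pixel offset relative to NIR, reproducing the
inter-lens misregistration the analysis has to undo.

A cohort wraps scenes into a germplasm × session design in which the green
fraction of each germplasm's canopy declines along a logistic senescence curve,
so the ground-truth greenness ranking at any session is known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .alignment import BandMeta
from .errors import GeometryError, InvalidParameterError
from .geometry import Rect

MS_BANDS = ("blue", "green", "red", "rededge", "nir")
RGB_CHANNELS = ("red", "green", "blue")

#: smoothing scale (px) of the canopy / green blob fields; grass-blade texture
CANOPY_FIELD_SIGMA = 2.0
GREEN_FIELD_SIGMA = 1.5


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SpectralProfile:
    """Per-band surface reflectance of one scene material, unitless in [0, 1]."""

    blue: float
    green: float
    red: float
    rededge: float
    nir: float

    def __post_init__(self) -> None:
        for band in MS_BANDS:
            v = getattr(self, band)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(
                    f"reflectance {band}={v} outside [0, 1]"
                )

    def band(self, name: str) -> float:
        return float(getattr(self, name))

    def as_array(self, bands: Sequence[str] = MS_BANDS) -> np.ndarray:
        return np.array([self.band(b) for b in bands], dtype=float)


#: healthy foliage: green visible peak, strong NIR plateau (nir > red, green > red)
GREEN_FOLIAGE = SpectralProfile(blue=0.04, green=0.22, red=0.06, rededge=0.35, nir=0.55)
#: browned foliage: red >= green; NIR stays high (leaf structure, not pigment)
SENESCENT_FOLIAGE = SpectralProfile(blue=0.10, green=0.16, red=0.20, rededge=0.42, nir=0.48)
#: sandy soil: spectrally flat within +/-0.05
SOIL = SpectralProfile(blue=0.18, green=0.20, red=0.22, rededge=0.21, nir=0.22)
#: green-tinted ground confounder (moss over sand); high ExG, soil-like NIR
MOSS = SpectralProfile(blue=0.12, green=0.26, red=0.14, rededge=0.22, nir=0.24)


@dataclass(frozen=True)
class TarpPanel:
    """A uniform-reflectance calibration panel: flat spectrum across all bands."""

    rect: Rect
    reflectance: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.reflectance <= 1.0):
            raise InvalidParameterError(
                f"panel reflectance {self.reflectance} outside [0, 1]"
            )


def default_panels() -> tuple[TarpPanel, ...]:
    return tuple(
        TarpPanel(Rect(10, 30 + i * 90, 20, 20), r)
        for i, r in enumerate((0.05, 0.20, 0.40, 0.60))
    )


@dataclass(frozen=True)
class SceneParams:
    """Full parameterization of one synthetic scene.

    DN response is linear per multispectral band (``dn = ms_gain·R + ms_bias``,
    16-bit container) and exponential for RGB (``dn = rgb_a·exp(rgb_b·R)``,
    8-bit).  ``red_offset`` is the (dy, dx) displacement applied to the RED
    band content relative to the NIR frame.
    """

    height: int = 300
    width: int = 400
    cell_box: Rect = field(default_factory=lambda: Rect(80, 120, 210, 260))
    canopy_fraction: float = 0.85
    green_fraction: float = 0.90
    green_profile: SpectralProfile = GREEN_FOLIAGE
    senescent_profile: SpectralProfile = SENESCENT_FOLIAGE
    soil_profile: SpectralProfile = SOIL
    moss_profile: SpectralProfile = MOSS
    moss_enabled: bool = False
    moss_fraction: float = 0.05
    panels: tuple[TarpPanel, ...] = field(default_factory=default_panels)
    ms_gain: float = 200.0
    ms_bias: float = 10.0
    rgb_a: float = 25.0
    rgb_b: float = 3.8
    noise_sd: float = 2.0
    red_offset: tuple[int, int] = (2, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise InvalidParameterError("image dimensions must be positive")
        if not self.cell_box.within((self.height, self.width)):
            raise GeometryError(
                f"cell box {self.cell_box} outside {self.height}x{self.width} image"
            )
        for name in ("canopy_fraction", "green_fraction", "moss_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.ms_gain <= 0 or self.rgb_a <= 0 or self.rgb_b == 0:
            raise InvalidParameterError("forward-model coefficients out of domain")
        for p in self.panels:
            p.rect.require_within((self.height, self.width), "tarp panel")
            if p.rect.intersects(self.cell_box):
                raise GeometryError(f"tarp panel {p.rect} overlaps the cell box")
        gp, sp, soil = self.green_profile, self.senescent_profile, self.soil_profile
        if not (gp.nir > gp.red and gp.green > gp.red):
            raise InvalidParameterError("green profile must have nir > red, green > red")
        if not sp.red >= sp.green:
            raise InvalidParameterError("senescent profile must have red >= green")
        vals = soil.as_array()
        if vals.max() - vals.min() > 0.05:
            raise InvalidParameterError("soil profile must be flat within 0.05")


@dataclass
class SceneTruth:
    """Ground truth for one generated scene."""

    canopy_mask: np.ndarray  # bool (H, W)
    green_mask: np.ndarray  # bool (H, W), subset of canopy_mask
    green_fraction: float  # |green| / |canopy|, 0 when canopy empty
    reflectance: dict[str, np.ndarray]  # registered per-band reflectance


@dataclass
class BandStack:
    """Raw per-scene DN rasters plus the metadata the pipeline consumes."""

    bands: dict[str, np.ndarray]  # uint16 (H, W) per multispectral band
    rgb: np.ndarray  # uint8 (H, W, 3), RGB channel order
    band_meta: dict[str, BandMeta]
    panels: tuple[TarpPanel, ...]
    cell_box: Rect
    params: SceneParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["nir"].shape


# ---------------------------------------------------------------------------
# senescence model


def senescence_fraction(t: float, m: float, s: float) -> float:
    """Programmed green fraction at session time ``t``.

    Logistic decline ``1 / (1 + exp((t - m) / s))``: ``m`` is the session time
    at which half the canopy has browned, ``s`` (> 0) the decline timescale.
    """
    if s <= 0:
        raise InvalidParameterError(f"senescence rate must be > 0, got {s}")
    z = (t - m) / s
    if z > 0:  # avoid overflow for extreme arguments
        e = math.exp(-z)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(z))


# ---------------------------------------------------------------------------
# scene generation


def _blob_pick(rng: np.random.Generator, eligible: np.ndarray, count: int,
               sigma: float) -> np.ndarray:
    """Pick exactly ``count`` eligible pixels as the top of a smoothed noise field.

    Thresholding a Gaussian-smoothed white-noise field yields a spatially
    coherent blob pattern; taking the top-``count`` order statistics makes the
    realized pixel count exact.
    """
    out = np.zeros(eligible.shape, dtype=bool)
    if count <= 0:
        return out
    field_ = ndimage.gaussian_filter(rng.standard_normal(eligible.shape), sigma)
    vals = np.where(eligible, field_, -np.inf)
    flat = vals.ravel()
    idx = np.argpartition(flat, flat.size - count)[flat.size - count:]
    out.ravel()[idx] = True
    return out & eligible


def _shift_fill(raster: np.ndarray, offset: tuple[int, int], fill: float) -> np.ndarray:
    """Translate content by (dy, dx); exposed border takes ``fill``."""
    dy, dx = offset
    out = np.full_like(raster, fill)
    h, w = raster.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = raster[src_r, src_c]
    return out


def _quantize(values: np.ndarray, lo: int, hi: int, dtype) -> np.ndarray:
    return np.clip(np.rint(values), lo, hi).astype(dtype)


def generate_scene(params: SceneParams) -> tuple[BandStack, SceneTruth]:
    """Render one scene: reflectance painting -> forward camera model -> DN stack.

    Deterministic given ``params.seed``.  The RED band raster is the only one
    whose content is displaced (by ``params.red_offset``) relative to the
    shared frame; the exposed border is filled with soil, as if the scene
    continued beyond the cell.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    shape = (h, w)

    cell = np.zeros(shape, dtype=bool)
    cell[params.cell_box.slices()] = True
    n_canopy = int(round(params.canopy_fraction * params.cell_box.area))
    canopy = _blob_pick(rng, cell, n_canopy, CANOPY_FIELD_SIGMA)
    n_green = int(round(params.green_fraction * canopy.sum()))
    green = _blob_pick(rng, canopy, n_green, GREEN_FIELD_SIGMA)
    moss = np.zeros(shape, dtype=bool)
    if params.moss_enabled:
        n_moss = int(round(params.moss_fraction * params.cell_box.area))
        moss = _blob_pick(rng, cell & ~canopy, n_moss, GREEN_FIELD_SIGMA)

    reflectance: dict[str, np.ndarray] = {}
    for band in MS_BANDS:
        r = np.full(shape, params.soil_profile.band(band))
        r[canopy] = params.senescent_profile.band(band)
        r[green] = params.green_profile.band(band)
        r[moss] = params.moss_profile.band(band)
        for panel in params.panels:
            r[panel.rect.slices()] = panel.reflectance
        reflectance[band] = r

    def dn_linear(r: np.ndarray) -> np.ndarray:
        dn = params.ms_gain * r + params.ms_bias
        if params.noise_sd > 0:
            dn = dn + rng.normal(0.0, params.noise_sd, shape)
        return _quantize(dn, 0, 65535, np.uint16)

    bands: dict[str, np.ndarray] = {}
    for band in MS_BANDS:
        r = reflectance[band]
        if band == "red":
            r = _shift_fill(r, params.red_offset, params.soil_profile.red)
        bands[band] = dn_linear(r)

    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for ch, band in enumerate(RGB_CHANNELS):
        dn = params.rgb_a * np.exp(params.rgb_b * reflectance[band])
        if params.noise_sd > 0:
            dn = dn + rng.normal(0.0, params.noise_sd, shape)
        rgb[..., ch] = _quantize(dn, 0, 255, np.uint8)

    dy, dx = params.red_offset
    meta = {b: BandMeta(band=b, center_y=0.0, center_x=0.0) for b in MS_BANDS}
    meta["red"] = BandMeta(band="red", center_y=float(dy), center_x=float(dx))

    n_can = int(canopy.sum())
    truth = SceneTruth(
        canopy_mask=canopy,
        green_mask=green,
        green_fraction=(green.sum() / n_can) if n_can else 0.0,
        reflectance=reflectance,
    )
    stack = BandStack(
        bands=bands,
        rgb=rgb,
        band_meta=meta,
        panels=params.panels,
        cell_box=params.cell_box,
        params=params,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortDesign:
    """Germplasm × session layout with per-germplasm senescence parameters.

    Session time is the 1-based session index.  ``midpoints[g]``/``rates[g]``
    set the logistic senescence curve of germplasm ``g``; the default spreads
    midpoints across the five-session window so the cohort spans vigorous to
    rapidly browning material.
    """

    germplasm_ids: tuple[str, ...] = tuple(f"g{i:02d}" for i in range(1, 21))
    sessions: int = 5
    replicates: int = 4
    scenes_per_session: int = 57
    midpoints: tuple[float, ...] | None = None
    rates: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sessions < 2:
            raise InvalidParameterError("need at least 2 sessions")
        if self.replicates < 2:
            raise InvalidParameterError("need at least 2 replicates")
        if self.scenes_per_session < 1:
            raise InvalidParameterError("need at least 1 scene per session")
        n = len(self.germplasm_ids)
        if n < 2:
            raise InvalidParameterError("need at least 2 germplasm")
        m = self.resolved_midpoints()
        s = self.resolved_rates()
        if len(m) != n or len(s) != n:
            raise InvalidParameterError("midpoints/rates length must match germplasm")
        if not all(math.isfinite(v) for v in m):
            raise InvalidParameterError("midpoints must be finite")
        if not all(math.isfinite(v) and v > 0 for v in s):
            raise InvalidParameterError("rates must be finite and > 0")

    def resolved_midpoints(self) -> tuple[float, ...]:
        if self.midpoints is not None:
            return tuple(float(v) for v in self.midpoints)
        n = len(self.germplasm_ids)
        return tuple(np.linspace(1.5, 4.5, n))

    def resolved_rates(self) -> tuple[float, ...]:
        if self.rates is not None:
            return tuple(float(v) for v in self.rates)
        return tuple(0.8 for _ in self.germplasm_ids)


@dataclass(frozen=True)
class SceneRecord:
    """One scene slot of a cohort: which germplasm, when, and how to render it."""

    session: int
    scene_index: int
    germplasm: str
    green_fraction: float
    params: SceneParams


def generate_cohort(
    design: CohortDesign,
    template: SceneParams | None = None,
    seed: int = 0,
    gain_drift_range: tuple[float, float] = (0.85, 1.15),
) -> tuple[list[SceneRecord], pd.DataFrame]:
    """Lay out a cohort: one scene record per scene slot per session.

    Scene slots cycle over germplasm, so with 57 slots and 20 germplasm each
    germplasm appears 2–3 times per session.  Illumination drift is modeled as
    a per-session multiplicative factor on the camera gains (the calibration
    stage is expected to undo it); drift factors and per-scene seeds all derive
    from ``seed``.  Returns the records plus a truth table of programmed green
    fractions.
    """
    template = template if template is not None else SceneParams()
    rng = np.random.default_rng(seed)
    lo, hi = gain_drift_range
    if lo > hi or lo <= 0:
        raise InvalidParameterError("invalid gain drift range")
    drift = rng.uniform(lo, hi, design.sessions)
    midpoints = design.resolved_midpoints()
    rates = design.resolved_rates()
    n_g = len(design.germplasm_ids)

    records: list[SceneRecord] = []
    rows: list[dict] = []
    for si in range(design.sessions):
        session = si + 1
        for scene_index in range(design.scenes_per_session):
            gi = scene_index % n_g
            germplasm = design.germplasm_ids[gi]
            gf = senescence_fraction(float(session), midpoints[gi], rates[gi])
            scene_seed = int(rng.integers(0, 2**31))
            params = replace(
                template,
                green_fraction=gf,
                ms_gain=template.ms_gain * drift[si],
                rgb_a=template.rgb_a * drift[si],
                seed=scene_seed,
            )
            records.append(SceneRecord(session, scene_index, germplasm, gf, params))
            rows.append(
                {
                    "session": session,
                    "scene": scene_index,
                    "germplasm": germplasm,
                    "midpoint": midpoints[gi],
                    "rate": rates[gi],
                    "green_fraction": gf,
                    "seed": scene_seed,
                }
            )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scene I/O (TIFF per band, PNG composite, JSON sidecar)


def write_scene(directory: str | Path, stack: BandStack,
                truth: SceneTruth | None = None) -> None:
    """Write a scene to disk: single-band 16-bit TIFFs, 8-bit RGB PNG, JSON meta."""
    import json

    import imageio.v3 as iio
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for band, raster in stack.bands.items():
        tifffile.imwrite(directory / f"band_{band}.tif", raster)
    iio.imwrite(directory / "rgb.png", stack.rgb)
    meta = {
        "band_meta": {
            b: {"center_y": m.center_y, "center_x": m.center_x}
            for b, m in stack.band_meta.items()
        },
        "panels": [
            {
                "rect": [p.rect.row0, p.rect.col0, p.rect.height, p.rect.width],
                "reflectance": p.reflectance,
            }
            for p in stack.panels
        ],
        "cell_box": [
            stack.cell_box.row0,
            stack.cell_box.col0,
            stack.cell_box.height,
            stack.cell_box.width,
        ],
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    if truth is not None:
        iio.imwrite(
            directory / "truth_canopy.png",
            (truth.canopy_mask.astype(np.uint8) * 255),
        )
        iio.imwrite(
            directory / "truth_green.png",
            (truth.green_mask.astype(np.uint8) * 255),
        )
        (directory / "truth.json").write_text(
            json.dumps({"green_fraction": truth.green_fraction})
        )


def read_scene(directory: str | Path) -> BandStack:
    """Read a scene written by :func:`write_scene`."""
    import json

    import imageio.v3 as iio
    import tifffile

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    bands = {
        band: tifffile.imread(directory / f"band_{band}.tif") for band in MS_BANDS
    }
    rgb = np.asarray(iio.imread(directory / "rgb.png"))
    band_meta = {
        b: BandMeta(band=b, center_y=m["center_y"], center_x=m["center_x"])
        for b, m in meta["band_meta"].items()
    }
    panels = tuple(
        TarpPanel(Rect(*p["rect"]), p["reflectance"]) for p in meta["panels"]
    )
    cell_box = Rect(*meta["cell_box"])
    h, w = bands["nir"].shape
    params = SceneParams(height=h, width=w, cell_box=cell_box, panels=panels)
    return BandStack(
        bands=bands,
        rgb=rgb,
        band_meta=band_meta,
        panels=panels,
        cell_box=cell_box,
        params=params,
    )
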