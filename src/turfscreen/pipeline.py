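"""End-to-end study orchestration: simulate → calibrate → align → segment →
measure → rank.

`run_study` executes the whole screening analysis for a configured cohort and
returns (and optionally writes) the long-format observation table, per-session
omnibus tests, ranked mean ± sd tables with compact letters, and per-session
correlations between green cover and each vegetation index.  Per-cell failures
(degenerate scenes, empty masks) degrade to missing records rather than
aborting the run; every source of randomness derives from the single root
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import alignment, greencover, radiometric, scenesim, segmentation, vegindices
from .errors import ConfigError, DataError, TurfscreenError, UndefinedStatisticError
from .geometry import Rect
from .groupstats import GroupSample, kruskal_wallis, pearson_r, rank_letter_table

logger = logging.getLogger(__name__)

METRICS = ("gcp",) + vegindices.INDEX_IDS


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class StudyConfig:
    """Everything a study run needs; validated on construction."""

    scene: scenesim.SceneParams = field(default_factory=scenesim.SceneParams)
    cohort: scenesim.CohortDesign = field(default_factory=scenesim.CohortDesign)
    roi_shape: tuple[int, int] = greencover.DEFAULT_ROI_SHAPE
    roi_count: int = greencover.DEFAULT_ROI_COUNT
    explicit_rois: tuple[Rect, ...] | None = None
    vi: vegindices.VIParams = field(default_factory=vegindices.VIParams)
    alpha: float = 0.05
    seed: int = 0
    align_mode: str = "metadata"  # or "estimate"
    max_shift: int = 10
    gain_drift_range: tuple[float, float] = (0.85, 1.15)
    exg_normalized: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError(f"alpha={self.alpha} outside (0, 1]")
        if self.align_mode not in ("metadata", "estimate"):
            raise ConfigError(f"unknown align_mode {self.align_mode!r}")
        if self.roi_count != self.cohort.replicates:
            raise ConfigError(
                "roi_count must equal cohort.replicates (each ROI is one replicate)"
            )
        # fail fast on infeasible ROI geometry rather than mid-run
        greencover.place_rois(self.scene.cell_box, self.roi_shape, self.roi_count,
                              explicit=self.explicit_rois)

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if isinstance(obj, Rect):
                return [obj.row0, obj.col0, obj.height, obj.width]
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return convert(self)  # type: ignore[return-value]

    @staticmethod
    def from_dict(raw: dict[str, Any]) -> "StudyConfig":
        try:
            kwargs: dict[str, Any] = {}
            if "scene" in raw:
                s = dict(raw["scene"])
                if "cell_box" in s:
                    s["cell_box"] = Rect(*s["cell_box"])
                if "panels" in s:
                    s["panels"] = tuple(
                        scenesim.TarpPanel(Rect(*p["rect"]), p["reflectance"])
                        for p in s["panels"]
                    )
                for prof in ("green_profile", "senescent_profile",
                             "soil_profile", "moss_profile"):
                    if prof in s:
                        s[prof] = scenesim.SpectralProfile(**s[prof])
                if "red_offset" in s:
                    s["red_offset"] = tuple(s["red_offset"])
                kwargs["scene"] = scenesim.SceneParams(**s)
            if "cohort" in raw:
                c = dict(raw["cohort"])
                for key in ("germplasm_ids", "midpoints", "rates"):
                    if c.get(key) is not None:
                        c[key] = tuple(c[key])
                kwargs["cohort"] = scenesim.CohortDesign(**c)
            if "vi" in raw:
                kwargs["vi"] = vegindices.VIParams(**raw["vi"])
            if "explicit_rois" in raw and raw["explicit_rois"] is not None:
                kwargs["explicit_rois"] = tuple(
                    Rect(*r) for r in raw["explicit_rois"]
                )
            for key in ("roi_shape", "gain_drift_range"):
                if key in raw:
                    kwargs[key] = tuple(raw[key])
            for key in ("roi_count", "alpha", "seed", "align_mode", "max_shift",
                        "exg_normalized"):
                if key in raw:
                    kwargs[key] = raw[key]
            return StudyConfig(**kwargs)
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"invalid study configuration: {exc}") from exc

    @staticmethod
    def from_yaml(path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
        return StudyConfig.from_dict(raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-scene processing


def _displaced_panels(panels, dy: int, dx: int, shape: tuple[int, int]):
    """Panel rectangles as they appear in a band whose content is displaced
    by (dy, dx); clipped to the raster bounds."""
    out = []
    for panel in panels:
        r = panel.rect
        row0 = max(r.row0 + dy, 0)
        col0 = max(r.col0 + dx, 0)
        row1 = min(r.row1 + dy, shape[0])
        col1 = min(r.col1 + dx, shape[1])
        if row1 - row0 < 1 or col1 - col0 < 1:
            raise DataError(
                f"panel {r} displaced by ({dy}, {dx}) leaves the image"
            )
        out.append(scenesim.TarpPanel(
            Rect(row0, col0, row1 - row0, col1 - col0), panel.reflectance
        ))
    return tuple(out)


def calibrate_stack(stack: scenesim.BandStack,
                    red_displacement: tuple[int, int] = (0, 0)
                    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Empirical-line calibration of every band plus the equalized RGB image.

    Multispectral bands are fitted linearly, RGB channels exponentially,
    against the tarp panels in frame; calibrated RGB reflectance is re-scaled
    to 8 bits and histogram-equalized for the color-index segmentation.
    ``red_displacement`` is the (dy, dx) content displacement of the RED band,
    so its panel pixels are sampled in the RED frame rather than the nominal
    one.
    """
    reflectance: dict[str, np.ndarray] = {}
    for band in scenesim.MS_BANDS:
        panels = stack.panels
        if band == "red" and red_displacement != (0, 0):
            panels = _displaced_panels(stack.panels, *red_displacement,
                                       shape=stack.shape)
        obs = radiometric.panel_observations(stack.bands[band], band, panels)
        model = radiometric.fit_empirical_line(obs, form="linear")
        reflectance[band] = radiometric.apply_calibration(
            stack.bands[band], model, band=band
        )
    rgb_refl = np.empty(stack.rgb.shape, dtype=float)
    for ch, band in enumerate(scenesim.RGB_CHANNELS):
        obs = radiometric.panel_observations(
            stack.rgb[..., ch], f"rgb-{band}", stack.panels
        )
        model = radiometric.fit_empirical_line(obs, form="exponential")
        rgb_refl[..., ch] = radiometric.apply_calibration(
            stack.rgb[..., ch], model, band=f"rgb-{band}"
        )
    rgb8 = np.clip(np.rint(np.nan_to_num(rgb_refl) * 255.0), 0, 255).astype(np.uint8)
    rgb_eq = radiometric.equalize_histogram(rgb8)
    return reflectance, rgb_eq


def resolve_red_offset(stack: scenesim.BandStack, mode: str = "metadata",
                       max_shift: int = 10) -> alignment.PixelOffset:
    """Corrective RED→NIR shift from metadata, or estimated from the DN
    rasters (gradient-magnitude SSD search) when metadata is absent or
    estimation is forced."""
    offset = None
    if mode == "metadata":
        offset = alignment.offset_from_metadata(
            stack.band_meta.get("red"), stack.band_meta.get("nir")
        )
    if offset is None:
        offset = alignment.estimate_offset(
            stack.bands["nir"], stack.bands["red"], max_shift=max_shift,
            on_gradient=True,
        )
    return offset


def measure_scene(stack: scenesim.BandStack, config: StudyConfig,
                  germplasm: str, session: int
                  ) -> tuple[list[greencover.GcpRecord], list[vegindices.ViRecord]]:
    """Run align → calibrate → equalize → segment → GCP + VI means for one scene.

    The RED/NIR offset is resolved first so the RED band's calibration panels
    can be sampled in the RED frame; the corrective shift itself is applied to
    the calibrated RED reflectance.
    """
    offset = resolve_red_offset(stack, mode=config.align_mode,
                                max_shift=config.max_shift)
    reflectance, rgb_eq = calibrate_stack(
        stack, red_displacement=(-offset.dy, -offset.dx)
    )
    red_aligned = alignment.shift_band(reflectance["red"], offset)
    canopy, green = segmentation.make_masks(
        reflectance["nir"], rgb_eq, normalized_exg=config.exg_normalized
    )
    rois = greencover.place_rois(stack.cell_box, config.roi_shape,
                                 config.roi_count, explicit=config.explicit_rois)
    gcp_records = greencover.green_cover_percent(
        canopy, green, rois, germplasm=germplasm, session=session
    )
    vi_bands = {
        "nir": reflectance["nir"],
        "red": red_aligned,
        "rededge": reflectance["rededge"],
        "blue": reflectance["blue"],
    }
    vi_records: list[vegindices.ViRecord] = []
    for index in vegindices.INDEX_IDS:
        raster = vegindices.compute_vi(vi_bands, index, config.vi)
        vi_records.extend(
            vegindices.roi_masked_mean(raster, canopy, rois, index=index,
                                       germplasm=germplasm, session=session)
        )
    return gcp_records, vi_records


# ---------------------------------------------------------------------------
# study stages


def _observation_rows(record: scenesim.SceneRecord, config: StudyConfig,
                      replicate_base: int) -> list[dict[str, Any]]:
    rows: list[dict[str, Any]] = []
    try:
        stack, _ = scenesim.generate_scene(record.params)
        gcp_records, vi_records = measure_scene(
            stack, config, record.germplasm, record.session
        )
    except TurfscreenError as exc:
        logger.warning(
            "scene %s/%s (%s) failed: %s; recording missing values",
            record.session, record.scene_index, record.germplasm, exc,
        )
        for rep in range(config.roi_count):
            for metric in METRICS:
                rows.append(
                    {
                        "germplasm": record.germplasm,
                        "session": record.session,
                        "scene": record.scene_index,
                        "replicate": replicate_base + rep,
                        "metric": metric,
                        "value": float("nan"),
                        "valid": False,
                    }
                )
        return rows
    for rec in gcp_records:
        rows.append(
            {
                "germplasm": rec.germplasm,
                "session": rec.session,
                "scene": record.scene_index,
                "replicate": replicate_base + rec.replicate,
                "metric": "gcp",
                "value": rec.gcp,
                "valid": rec.valid,
            }
        )
    for rec in vi_records:
        rows.append(
            {
                "germplasm": rec.germplasm,
                "session": rec.session,
                "scene": record.scene_index,
                "replicate": replicate_base + rec.replicate,
                "metric": rec.index,
                "value": rec.value,
                "valid": rec.valid,
            }
        )
    return rows


def run_records(records: Sequence[scenesim.SceneRecord],
                config: StudyConfig) -> pd.DataFrame:
    """Process scene records into the long-format observation table.

    Replicate indices are global per germplasm × session: when a germplasm
    appears in several scenes of a session, its replicate count grows in
    blocks of ``roi_count``.
    """
    rows: list[dict[str, Any]] = []
    seen: dict[tuple[str, int], int] = {}
    for record in records:
        key = (record.germplasm, record.session)
        occurrence = seen.get(key, 0)
        seen[key] = occurrence + 1
        rows.extend(_observation_rows(record, config,
                                      replicate_base=occurrence * config.roi_count))
    return pd.DataFrame(
        rows,
        columns=["germplasm", "session", "scene", "replicate", "metric",
                 "value", "valid"],
    )


def run_session(config: StudyConfig, session: int) -> pd.DataFrame:
    """Observation rows for a single session of the configured cohort."""
    records, _ = scenesim.generate_cohort(
        config.cohort, config.scene, seed=config.seed,
        gain_drift_range=config.gain_drift_range,
    )
    records = [r for r in records if r.session == session]
    if not records:
        raise ConfigError(f"session {session} not in the configured design")
    return run_records(records, config)


def compute_statistics(observations: pd.DataFrame, alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per session × metric statistics from the observation table.

    Returns (omnibus, letters, correlation): Kruskal–Wallis H/df/p per session
    and metric; ranked mean ± sd with compact letters; and per-session Pearson
    correlation of per-germplasm mean GCP against each vegetation index mean.
    """
    omnibus_rows, letter_frames, corr_rows = [], [], []
    sessions = sorted(observations["session"].unique())
    for session in sessions:
        chunk = observations[(observations.session == session) & observations.valid]
        for metric in METRICS:
            sub = chunk[chunk.metric == metric]
            groups = []
            for germplasm, vals in sub.groupby("germplasm")["value"]:
                v = vals.to_numpy(dtype=float)
                v = v[np.isfinite(v)]
                if v.size >= 2:
                    groups.append(GroupSample(germplasm, v))
            if len(groups) < 2:
                logger.warning("session %s metric %s: < 2 usable groups; skipped",
                               session, metric)
                continue
            omnibus = kruskal_wallis(groups)
            omnibus_rows.append(
                {
                    "session": session,
                    "metric": metric,
                    "df": omnibus.df,
                    "H": omnibus.statistic,
                    "p_value": omnibus.p_value,
                }
            )
            table = rank_letter_table(groups, alpha=alpha)
            table.insert(0, "metric", metric)
            table.insert(0, "session", session)
            letter_frames.append(table)

        means = (
            chunk.groupby(["germplasm", "metric"])["value"].mean().unstack()
        )
        for index in vegindices.INDEX_IDS:
            row = {"session": session, "metric": index,
                   "r": float("nan"), "r2": float("nan"), "p_value": float("nan")}
            if "gcp" in means.columns and index in means.columns:
                paired = means[["gcp", index]].dropna()
                if len(paired) >= 3:
                    try:
                        r, r2, p = pearson_r(paired["gcp"], paired[index])
                        row.update(r=r, r2=r2, p_value=p)
                    except UndefinedStatisticError:
                        pass
            corr_rows.append(row)

    letters = (
        pd.concat(letter_frames, ignore_index=True)
        if letter_frames
        else pd.DataFrame(columns=["session", "metric", "germplasm",
                                   "mean", "sd", "letters"])
    )
    return pd.DataFrame(omnibus_rows), letters, pd.DataFrame(corr_rows)


@dataclass
class StudyResult:
    observations: pd.DataFrame
    truth: pd.DataFrame
    omnibus: pd.DataFrame
    letters: pd.DataFrame
    correlation: pd.DataFrame
    manifest: dict[str, Any]


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Run the full screening study described by ``config``.

    Deterministic given the configuration (all randomness flows from
    ``config.seed``); when ``out_dir`` is given, every table plus a manifest
    and a config echo are written there.
    """
    records, truth = scenesim.generate_cohort(
        config.cohort, config.scene, seed=config.seed,
        gain_drift_range=config.gain_drift_range,
    )
    observations = run_records(records, config)
    omnibus, letters, correlation = compute_statistics(observations, config.alpha)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sessions": config.cohort.sessions,
        "germplasm": len(config.cohort.germplasm_ids),
        "n_scene_records": len(records),
        "n_observations": int(len(observations)),
        "n_valid_observations": int(observations["valid"].sum()),
    }
    result = StudyResult(
        observations=observations,
        truth=truth,
        omnibus=omnibus,
        letters=letters,
        correlation=correlation,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, config, out_dir)
    return result


def write_outputs(result: StudyResult, config: StudyConfig,
                  out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.observations.to_csv(out / "observations.csv", index=False)
    result.truth.to_csv(out / "truth.csv", index=False)
    result.omnibus.to_csv(out / "omnibus.csv", index=False)
    result.letters.to_csv(out / "letters.csv", index=False)
    result.correlation.to_csv(out / "correlation.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )
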