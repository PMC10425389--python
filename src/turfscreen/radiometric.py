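"""Empirical-line radiometric calibration and RGB histogram equalization.

Each band is calibrated against reference tarp panels of known surface
reflectance visible in the frame.  Multispectral bands use a linear model
fitted by least squares directly in reflectance-vs-DN space,
``R = gain·DN + bias``; RGB channels use an exponential sensor model
``DN = a·exp(b·R)``, fitted as a straight line in log-DN space
(``ln DN = ln a + b·R``) and inverted per pixel as ``R = ln(DN/a)/b``.
Recovered reflectance is clipped to [0, 1]; pixels outside the exponential
domain (DN ≤ 0) become NaN.

Histogram equalization is the standard global CDF remap on 8-bit images,
applied per channel after calibration to brighten the dark calibrated RGB
composite before color-index segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigError, DegenerateInputError, InsufficientPanelsError

Form = Literal["linear", "exponential"]


@dataclass(frozen=True)
class PanelObservation:
    """One calibration panel seen in one band: known reflectance vs mean DN."""

    band: str
    reflectance: float
    dn: float  # mean DN over the panel rectangle

    def __post_init__(self) -> None:
        if not (0.0 <= self.reflectance <= 1.0):
            raise ConfigError(f"panel reflectance {self.reflectance} outside [0, 1]")
        if self.dn < 0:
            raise ConfigError(f"panel DN {self.dn} must be >= 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted DN → reflectance mapping for one band."""

    band: str
    form: Form
    gain: float = 0.0  # linear: R = gain·DN + bias
    bias: float = 0.0
    a: float = 1.0  # exponential: DN = a·exp(b·R)
    b: float = 0.0
    residual_rms: float = 0.0  # RMS of reflectance residuals on the fit panels


def fit_empirical_line(panels: Sequence[PanelObservation],
                       form: Form = "linear") -> CalibrationModel:
    """Least-squares empirical-line fit over ≥ 2 spectrally distinct panels."""
    if len(panels) < 2:
        raise InsufficientPanelsError(
            f"need at least 2 panels, got {len(panels)}"
        )
    bands = {p.band for p in panels}
    if len(bands) != 1:
        raise ConfigError(f"panels span multiple bands: {sorted(bands)}")
    band = panels[0].band
    dn = np.array([p.dn for p in panels], dtype=float)
    refl = np.array([p.reflectance for p in panels], dtype=float)

    if form == "linear":
        if np.ptp(dn) == 0:
            raise InsufficientPanelsError(
                "degenerate panel set: zero DN spread between panels"
            )
        design = np.column_stack([dn, np.ones_like(dn)])
        (gain, bias), *_ = np.linalg.lstsq(design, refl, rcond=None)
        fitted = gain * dn + bias
        rms = float(np.sqrt(np.mean((fitted - refl) ** 2)))
        return CalibrationModel(band=band, form="linear", gain=float(gain),
                                bias=float(bias), residual_rms=rms)

    if form == "exponential":
        if np.any(dn <= 0):
            raise InsufficientPanelsError(
                "exponential fit requires all panel DN > 0"
            )
        if np.ptp(refl) == 0:
            raise InsufficientPanelsError(
                "degenerate panel set: zero reflectance spread between panels"
            )
        design = np.column_stack([refl, np.ones_like(refl)])
        (b, ln_a), *_ = np.linalg.lstsq(design, np.log(dn), rcond=None)
        if b == 0:
            raise InsufficientPanelsError("degenerate exponential fit (b = 0)")
        a = float(np.exp(ln_a))
        fitted_r = (np.log(dn) - ln_a) / b
        rms = float(np.sqrt(np.mean((fitted_r - refl) ** 2)))
        return CalibrationModel(band=band, form="exponential", a=a, b=float(b),
                                residual_rms=rms)

    raise ConfigError(f"unknown calibration form {form!r}")


def apply_calibration(raster: np.ndarray, model: CalibrationModel,
                      band: str | None = None) -> np.ndarray:
    """Per-pixel DN → reflectance; output float, clipped to [0, 1], NaN invalid."""
    if band is not None and band != model.band:
        raise ConfigError(
            f"calibration model for band {model.band!r} applied to {band!r}"
        )
    dn = np.asarray(raster, dtype=float)
    if model.form == "linear":
        refl = model.gain * dn + model.bias
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            refl = np.where(dn > 0, np.log(dn / model.a) / model.b, np.nan)
    return np.clip(refl, 0.0, 1.0)


def panel_observations(raster: np.ndarray, band: str,
                       panels: Sequence) -> list[PanelObservation]:
    """Summarize each tarp panel as its mean DN over the panel rectangle."""
    obs = []
    for panel in panels:
        region = np.asarray(raster, dtype=float)[panel.rect.slices()]
        obs.append(
            PanelObservation(band=band, reflectance=panel.reflectance,
                             dn=float(np.nanmean(region)))
        )
    return obs


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit image, per channel.

    Level ``v`` maps to ``round((cdf(v) − cdf_min) / (N − cdf_min) × 255)``
    where ``cdf`` counts pixels at or below each level and ``cdf_min`` is the
    CDF at the lowest occupied level.  The mapping is monotone non-decreasing,
    so pixel brightness rank order is preserved; a constant channel is
    returned unchanged.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ConfigError("histogram equalization expects an 8-bit image")
    if img.ndim == 2:
        return _equalize_channel(img)
    if img.ndim == 3:
        out = np.empty_like(img)
        for c in range(img.shape[2]):
            out[..., c] = _equalize_channel(img[..., c])
        return out
    raise ConfigError(f"expected 2-D or 3-D image, got ndim={img.ndim}")


def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    counts = np.bincount(channel.ravel(), minlength=256)
    cdf = np.cumsum(counts)
    cdf_min = cdf[np.nonzero(counts)[0][0]]
    n = channel.size
    if n == cdf_min:  # constant channel: degenerate histogram, identity
        return channel.copy()
    lut = np.rint((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[channel]
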