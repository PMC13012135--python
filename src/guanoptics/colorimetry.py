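"""Reflectance spectra to chromaticity, display color, and pixel mixing.

The macroscopic hue of a pixelated surface is the intensity-averaged sum of
the reflectances of its micron-scale color pixels; sufficiently diverse
pixels mix to white, the same way an RGB display does.  This module
integrates reflectance spectra to CIE 1931 tristimulus values under a
standard illuminant (default D65, 2-degree observer), converts to sRGB for
rendering, mixes pixel spectra, and measures chromatic distance to the
illuminant white point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _cie
from .tmm import ReflectanceSpectrum

__all__ = [
    "Chromaticity",
    "spectrum_to_chromaticity",
    "xyz_to_srgb",
    "mix_pixel_spectra",
    "chromatic_distance_to_white",
    "white_point",
]


@dataclass(frozen=True)
class Chromaticity:
    """CIE tristimulus values, (x, y) coordinates and an sRGB rendering.

    ``Y`` is on the 0-100 scale (perfect reflector = 100).  ``srgb`` is the
    gamma-encoded triplet clipped to [0, 1]; ``out_of_gamut`` records
    whether clipping occurred.
    """

    X: float
    Y: float
    Z: float
    x: float
    y: float
    srgb: tuple[float, float, float]
    out_of_gamut: bool


def _linear_to_srgb(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.power(np.clip(c, 0, None), 1 / 2.4) - 0.055)


def xyz_to_srgb(X: float, Y: float, Z: float) -> tuple[tuple[float, float, float], bool]:
    """XYZ (Y scale 0-100) to gamma-encoded sRGB with clipping + gamut flag."""
    lin = _cie.XYZ_TO_SRGB_LINEAR @ (np.array([X, Y, Z]) / 100.0)
    out_of_gamut = bool(np.any(lin < -1e-9) or np.any(lin > 1 + 1e-9))
    srgb = np.clip(_linear_to_srgb(np.clip(lin, 0.0, 1.0)), 0.0, 1.0)
    return (float(srgb[0]), float(srgb[1]), float(srgb[2])), out_of_gamut


def spectrum_to_chromaticity(
    spectrum: ReflectanceSpectrum,
    illuminant: str = "D65",
    observer: str = "cie_1931_2deg",
) -> Chromaticity:
    """Tristimulus integration of a reflectance spectrum.

    Normalized so a unit reflector has Y = 100 under the illuminant.  The
    spectrum must cover at least 400-700 nm; integration runs over its
    overlap with the 380-780 nm colorimetric range.
    """
    wl = spectrum.wavelengths
    if wl[0] > 400.0 or wl[-1] < 700.0:
        raise ValueError("spectrum must cover at least 400-700 nm for colorimetry")
    lo, hi = max(wl[0], 380.0), min(wl[-1], 780.0)
    sel = (wl >= lo) & (wl <= hi)
    w = wl[sel]
    refl = spectrum.reflectance[sel]
    cmf = _cie.cmf_on_grid(w, observer)
    spd = _cie.illuminant_on_grid(w, illuminant)
    k = 100.0 / np.trapezoid(spd * cmf[:, 1], w)
    XYZ = k * np.trapezoid((spd * refl)[:, None] * cmf, w, axis=0)
    X, Y, Z = (float(v) for v in XYZ)
    s = X + Y + Z
    if s <= 0:
        x = y = 0.0
    else:
        x, y = X / s, Y / s
    srgb, oog = xyz_to_srgb(X, Y, Z)
    return Chromaticity(X, Y, Z, x, y, srgb, oog)


def white_point(illuminant: str = "D65", observer: str = "cie_1931_2deg") -> tuple[float, float]:
    """(x, y) chromaticity of the illuminant itself (unit reflector)."""
    wl = np.arange(380.0, 780.5, 1.0)
    cmf = _cie.cmf_on_grid(wl, observer)
    spd = _cie.illuminant_on_grid(wl, illuminant)
    XYZ = np.trapezoid(spd[:, None] * cmf, wl, axis=0)
    return float(XYZ[0] / XYZ.sum()), float(XYZ[1] / XYZ.sum())


def mix_pixel_spectra(
    spectra: Sequence[ReflectanceSpectrum],
    weights: Sequence[float] | None = None,
) -> ReflectanceSpectrum:
    """Intensity-average a set of pixel spectra into one macroscopic spectrum.

    All spectra must share an identical wavelength grid (no silent
    resampling).  Weights default to equal and must sum to 1.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all spectra must share an identical wavelength grid")
    if weights is None:
        w = np.full(len(spectra), 1.0 / len(spectra))
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(spectra):
            raise ValueError("weights length must match number of spectra")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
    R = sum(wi * s.reflectance for wi, s in zip(w, spectra))
    T = sum(wi * s.transmittance for wi, s in zip(w, spectra))
    return ReflectanceSpectrum(wl, R, T, polarization=spectra[0].polarization)


def chromatic_distance_to_white(c: Chromaticity, illuminant: str = "D65") -> float:
    """Euclidean distance in (x, y) from the illuminant white point."""
    wx, wy = white_point(illuminant)
    return float(np.hypot(c.x - wx, c.y - wy))
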