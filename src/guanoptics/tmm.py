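"""Transfer-matrix optics of finite dielectric multilayer stacks.

A guanine platelet stack is modelled as a 1D sequence of homogeneous,
lossless, non-dispersive layers: high-index guanine platelets (n ~ 1.83)
separated by low-index cytoplasm gaps (n ~ 1.34), embedded in tissue of the
gap index on both sides.  The characteristic-matrix form of the transfer
matrix method gives the exact plane-wave reflectance and transmittance of
such a stack at any incidence angle and polarization.

Conventions
-----------
* Angles cross the public API in degrees; radians are internal.
* Wavelengths and thicknesses in nanometres.
* ``polarization`` is one of ``"s"``, ``"p"`` or ``"unpolarized"``
  (arithmetic mean of the s and p intensity reflectances).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalConstants",
    "StackGeometry",
    "ReflectanceSpectrum",
    "PeakMetrics",
    "EvanescentWaveError",
    "fresnel_coefficients",
    "stack_reflectance",
    "bragg_peak_wavelength",
    "volume_averaged_index",
    "peak_metrics",
    "default_wavelengths",
]

_POLARIZATIONS = ("s", "p", "unpolarized")


class EvanescentWaveError(ValueError):
    """Raised when refraction would require a complex (evanescent) angle."""


@dataclass(frozen=True)
class OpticalConstants:
    """Real refractive indices of the three media.

    Defaults are guanine's in-plane index against tissue/cytoplasm:
    n_platelet = 1.83, n_gap = n_ambient = 1.34.
    """

    n_platelet: float = 1.83
    n_gap: float = 1.34
    n_ambient: float = 1.34

    def __post_init__(self) -> None:
        for name in ("n_platelet", "n_gap", "n_ambient"):
            n = getattr(self, name)
            if not np.isreal(n) or n < 1.0:
                raise ValueError(f"{name} must be a real index >= 1, got {n!r}")


@dataclass(frozen=True)
class StackGeometry:
    """One multilayer pixel: ordered platelet and gap thicknesses plus orientation.

    The stack is bounded by ambient medium on both sides, so a stack of N
    platelets has N - 1 internal gaps.  ``orientation_polar`` is the angle of
    the stack normal to the surface normal (degrees); ``orientation_azimuth``
    its azimuth.
    """

    platelet_thicknesses: tuple[float, ...]
    gap_thicknesses: tuple[float, ...]
    orientation_polar: float = 0.0
    orientation_azimuth: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "platelet_thicknesses", tuple(float(t) for t in self.platelet_thicknesses)
        )
        object.__setattr__(
            self, "gap_thicknesses", tuple(float(t) for t in self.gap_thicknesses)
        )
        if len(self.platelet_thicknesses) < 1:
            raise ValueError("a stack needs at least one platelet")
        if len(self.gap_thicknesses) != len(self.platelet_thicknesses) - 1:
            raise ValueError(
                "number of gaps must be number of platelets - 1 "
                f"(got {len(self.gap_thicknesses)} gaps for "
                f"{len(self.platelet_thicknesses)} platelets)"
            )
        if any(t <= 0 for t in self.platelet_thicknesses + self.gap_thicknesses):
            raise ValueError("all thicknesses must be > 0")
        if not 0.0 <= self.orientation_polar <= 90.0:
            raise ValueError("orientation_polar must lie in [0, 90] degrees")

    @property
    def n_platelets(self) -> int:
        return len(self.platelet_thicknesses)

    def layer_sequence(self, optics: OpticalConstants) -> tuple[np.ndarray, np.ndarray]:
        """Interleaved (indices, thicknesses) of the internal layers."""
        n, d = [], []
        for i, t in enumerate(self.platelet_thicknesses):
            n.append(optics.n_platelet)
            d.append(t)
            if i < len(self.gap_thicknesses):
                n.append(optics.n_gap)
                d.append(self.gap_thicknesses[i])
        return np.asarray(n, dtype=float), np.asarray(d, dtype=float)

    def reversed(self) -> "StackGeometry":
        return replace(
            self,
            platelet_thicknesses=self.platelet_thicknesses[::-1],
            gap_thicknesses=self.gap_thicknesses[::-1],
        )


@dataclass
class ReflectanceSpectrum:
    """Reflectance/transmittance on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray
    polarization: str = "unpolarized"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        if self.wavelengths.size == 0:
            raise ValueError("empty wavelength grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not (
            self.wavelengths.shape == self.reflectance.shape == self.transmittance.shape
        ):
            raise ValueError("wavelengths, reflectance, transmittance must share a shape")
        if self.polarization not in _POLARIZATIONS:
            raise ValueError(f"polarization must be one of {_POLARIZATIONS}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "reflectance": self.reflectance,
                "transmittance": self.transmittance,
            }
        )

    def to_csv(self, path, metadata: dict | None = None) -> None:
        """Write `wavelength_nm,reflectance,transmittance` CSV; optional JSON sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {"polarization": self.polarization}
        if metadata:
            meta.update(metadata)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, default=str)
        )


@dataclass(frozen=True)
class PeakMetrics:
    """Location, height and width of the dominant reflectance peak."""

    peak_wavelength: float
    peak_reflectance: float
    fwhm: float | None
    defined: bool = True


def default_wavelengths(start: float = 300.0, stop: float = 800.0, step: float = 1.0) -> np.ndarray:
    """Default wavelength grid: 300-800 nm at 1 nm steps."""
    return np.arange(start, stop + 0.5 * step, step)


def _check_angle(theta_deg: float) -> float:
    theta = float(theta_deg)
    if not 0.0 <= theta < 90.0:
        raise ValueError(f"incidence angle must lie in [0, 90) degrees, got {theta}")
    return np.radians(theta)


def _refraction_cos(n_from: float, n_to: np.ndarray, sin_theta_from: float) -> np.ndarray:
    """Cosine of the refracted angle via Snell's law; errors on evanescence."""
    sin_t = n_from * sin_theta_from / n_to
    if np.any(sin_t > 1.0 + 1e-12):
        raise EvanescentWaveError(
            "refraction into the lower-index medium is evanescent at this angle"
        )
    return np.sqrt(np.clip(1.0 - sin_t**2, 0.0, None))


def fresnel_coefficients(
    n1: float, n2: float, theta1: float, polarization: str
) -> tuple[float, float]:
    """Amplitude reflection and transmission at a single planar interface.

    Parameters are the two real indices, the incidence angle in medium 1
    (degrees) and the polarization (``"s"`` or ``"p"``).  Returns ``(r, t)``.
    Raises :class:`EvanescentWaveError` beyond the critical angle.
    """
    if polarization not in ("s", "p"):
        raise ValueError("fresnel_coefficients needs polarization 's' or 'p'")
    if n1 < 1 or n2 < 1:
        raise ValueError("indices must be >= 1")
    th1 = _check_angle(theta1)
    c1 = np.cos(th1)
    c2 = float(_refraction_cos(n1, np.asarray(n2, dtype=float), np.sin(th1)))
    if polarization == "s":
        r = (n1 * c1 - n2 * c2) / (n1 * c1 + n2 * c2)
        t = 2 * n1 * c1 / (n1 * c1 + n2 * c2)
    else:
        r = (n2 * c1 - n1 * c2) / (n2 * c1 + n1 * c2)
        t = 2 * n1 * c1 / (n2 * c1 + n1 * c2)
    return float(r), float(t)


def _tilted_admittance(n: np.ndarray, cos_t: np.ndarray, polarization: str) -> np.ndarray:
    # Optical admittance in free-space units: n cos(theta) for s, n / cos(theta) for p.
    if polarization == "s":
        return n * cos_t
    return n / cos_t


def _rt_one_polarization(
    n_layers: np.ndarray,
    d_layers: np.ndarray,
    n_ambient: float,
    n_substrate: float,
    wavelengths: np.ndarray,
    theta_rad: float,
    polarization: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Characteristic-matrix product for one polarization, vectorized over wavelength."""
    sin0 = np.sin(theta_rad)
    cos0 = np.cos(theta_rad)
    eta0 = _tilted_admittance(np.asarray(n_ambient), np.asarray(cos0), polarization)
    cos_sub = _refraction_cos(n_ambient, np.asarray(n_substrate, dtype=float), sin0)
    eta_sub = _tilted_admittance(np.asarray(n_substrate), cos_sub, polarization)

    nw = wavelengths.size
    # Running product of layer characteristic matrices, per wavelength.
    m00 = np.ones(nw, dtype=complex)
    m01 = np.zeros(nw, dtype=complex)
    m10 = np.zeros(nw, dtype=complex)
    m11 = np.ones(nw, dtype=complex)
    for nj, dj in zip(n_layers, d_layers):
        cos_j = float(_refraction_cos(n_ambient, np.asarray(nj, dtype=float), sin0))
        eta_j = float(_tilted_admittance(np.asarray(nj), np.asarray(cos_j), polarization))
        delta = 2.0 * np.pi * nj * dj * cos_j / wavelengths
        c, s = np.cos(delta), np.sin(delta)
        a00, a01 = c, 1j * s / eta_j
        a10, a11 = 1j * eta_j * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    b = m00 + m01 * eta_sub
    c = m10 + m11 * eta_sub
    denom = eta0 * b + c
    r = (eta0 * b - c) / denom
    reflectance = np.abs(r) ** 2
    transmittance = 4.0 * eta0 * np.real(eta_sub) / np.abs(denom) ** 2
    return reflectance, transmittance


def stack_reflectance(
    stack: StackGeometry,
    optics: OpticalConstants = OpticalConstants(),
    wavelengths: Sequence[float] | np.ndarray | None = None,
    theta: float = 0.0,
    polarization: str = "unpolarized",
) -> ReflectanceSpectrum:
    """Exact reflectance/transmittance spectrum of one platelet stack.

    ``theta`` is the incidence angle in the ambient medium, measured from the
    stack normal, in degrees.  Unpolarized light is the arithmetic mean of
    the s and p intensity responses.  For the lossless default media the
    returned spectrum satisfies R + T = 1 to machine precision.
    """
    if polarization not in _POLARIZATIONS:
        raise ValueError(f"polarization must be one of {_POLARIZATIONS}")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    theta_rad = _check_angle(theta)
    n_layers, d_layers = stack.layer_sequence(optics)

    pols = ("s", "p") if polarization == "unpolarized" else (polarization,)
    R = np.zeros_like(wl)
    T = np.zeros_like(wl)
    for pol in pols:
        r, t = _rt_one_polarization(
            n_layers, d_layers, optics.n_ambient, optics.n_ambient, wl, theta_rad, pol
        )
        R += r
        T += t
    R /= len(pols)
    T /= len(pols)
    return ReflectanceSpectrum(wl, R, T, polarization=polarization)


def volume_averaged_index(
    t_platelet: float, t_gap: float, optics: OpticalConstants = OpticalConstants()
) -> float:
    """Thickness-weighted mean refractive index of one platelet + gap period."""
    if t_platelet < 0 or t_gap < 0 or (t_platelet == 0 and t_gap == 0):
        raise ValueError("thicknesses must be >= 0 and not both zero")
    return (t_platelet * optics.n_platelet + t_gap * optics.n_gap) / (t_platelet + t_gap)


def bragg_peak_wavelength(n_avg: float, pitch: float, theta: float) -> float:
    """First-order Bragg wavelength lambda = 2 n d cos(theta).

    ``theta`` is the propagation angle inside the effective medium, degrees.
    """
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    if not 0.0 <= theta <= 90.0:
        raise ValueError("theta must lie in [0, 90] degrees")
    return 2.0 * n_avg * pitch * np.cos(np.radians(theta))


def peak_metrics(spectrum: ReflectanceSpectrum) -> PeakMetrics:
    """Global-maximum peak position, height and interpolated FWHM.

    Ties break to the lowest wavelength.  A spectrum with no power returns
    an undefined-peak flag instead of raising.  The FWHM is found by linear
    interpolation of the half-height crossings nearest the peak; if either
    crossing is missing the width is reported as ``None``.
    """
    wl = spectrum.wavelengths
    refl = spectrum.reflectance
    i_peak = int(np.argmax(refl))  # argmax returns the first (lowest-wavelength) maximum
    r_peak = float(refl[i_peak])
    if r_peak <= 0.0:
        return PeakMetrics(float("nan"), 0.0, None, defined=False)
    half = r_peak / 2.0

    def _cross(side: str) -> float | None:
        if side == "left":
            idx = range(i_peak, 0, -1)
        else:
            idx = range(i_peak, len(wl) - 1)
        for i in idx:
            j = i - 1 if side == "left" else i + 1
            if (refl[i] - half) * (refl[j] - half) <= 0 and refl[j] <= half:
                # linear interpolation between grid points i and j
                frac = (half - refl[i]) / (refl[j] - refl[i])
                return float(wl[i] + frac * (wl[j] - wl[i]))
        return None

    left = _cross("left")
    right = _cross("right")
    fwhm = (right - left) if (left is not None and right is not None) else None
    return PeakMetrics(float(wl[i_peak]), r_peak, fwhm, defined=True)
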