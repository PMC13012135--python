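"""Orientation-ensemble averaging: the angle-independence mechanism.

A single multilayer stack is iridescent — its reflectance peak blue-shifts
with incidence angle.  Tissue containing many stacks with broadly
distributed orientations reflects the intensity average of the individual
stacks, each illuminated at its own local angle; because some stack is
always near-normal to the light, the ensemble peak barely moves as the
illumination rotates.  This module implements that mechanism: local
incidence geometry, ensemble spectra, angular sweeps, thickness noise,
leptokurtic incidence-angle sampling and the thickness x spacing
design-space map.

Stack normals are treated as unsigned axes (a dielectric platelet stack in a
symmetric ambient reflects identically from either face), so the local
incidence angle is folded into [0, 90]; only the degenerate grazing case is
flagged non-contributing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import t as student_t

from .structures import StackPopulation
from .tmm import (
    OpticalConstants,
    ReflectanceSpectrum,
    StackGeometry,
    default_wavelengths,
    peak_metrics,
    stack_reflectance,
)

__all__ = [
    "IlluminationGeometry",
    "AngularSweepResult",
    "local_incidence_angle",
    "ensemble_reflectance",
    "angular_sweep",
    "apply_thickness_noise",
    "sample_leptokurtic_angles",
    "design_space_map",
]

GRAZING_CUTOFF_DEG = 89.9  # local angles at/above this are non-contributing


@dataclass(frozen=True)
class IlluminationGeometry:
    """Global illumination direction: polar angle theta (deg, unrestricted,
    the sample may be rotated through a full circle) and azimuth (deg)."""

    theta: float = 0.0
    azimuth: float = 0.0

    def direction(self) -> np.ndarray:
        t = np.radians(self.theta)
        a = np.radians(self.azimuth)
        return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])


@dataclass
class AngularSweepResult:
    """Peak position and amplitude of the ensemble spectrum per angle."""

    thetas: np.ndarray
    peak_wavelengths: np.ndarray
    peak_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.peak_wavelengths = np.asarray(self.peak_wavelengths, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if not (len(self.thetas) == len(self.peak_wavelengths) == len(self.peak_amplitudes)):
            raise ValueError("sweep result arrays must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta_deg": self.thetas,
                "peak_wavelength_nm": self.peak_wavelengths,
                "peak_amplitude": self.peak_amplitudes,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _normal_axis(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    p = np.radians(polar_deg)
    a = np.radians(azimuth_deg)
    return np.array([np.sin(p) * np.cos(a), np.sin(p) * np.sin(a), np.cos(p)])


def local_incidence_angle(
    stack_orientation: tuple[float, float], illumination: IlluminationGeometry
) -> tuple[float, bool]:
    """Angle between the illumination direction and a stack's normal axis.

    Returns ``(angle_deg, contributing)`` with the angle folded into
    [0, 90]; ``contributing`` is False only in the degenerate grazing
    regime (angle >= 89.9 deg), where plane-wave reflectance is ill-defined
    for a finite stack.
    """
    n = _normal_axis(*stack_orientation)
    d = illumination.direction()
    cosang = abs(float(np.dot(n, d)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return angle, angle < GRAZING_CUTOFF_DEG


def ensemble_reflectance(
    population: StackPopulation,
    illumination: IlluminationGeometry = IlluminationGeometry(),
    wavelengths: np.ndarray | None = None,
    optics: OpticalConstants = OpticalConstants(),
    weighting: str = "cos",
) -> ReflectanceSpectrum:
    """Intensity-averaged unpolarized spectrum of a stack population.

    Each stack is evaluated at its local incidence angle and the ensemble
    is the weighted mean over the population.  The default ``"cos"``
    weighting multiplies each stack by the geometric cross-section it
    presents to the beam (proportional to the cosine of its local angle),
    which is what an intensity average over a volume of finite platelets
    measures; ``"equal"`` gives every stack the same weight regardless of
    orientation.  Non-contributing (grazing) stacks add zero reflectance
    and unit transmittance.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    if weighting not in ("cos", "equal"):
        raise ValueError("weighting must be 'cos' or 'equal'")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    R = np.zeros_like(wl)
    T = np.zeros_like(wl)
    wsum = 0.0
    n_contrib = 0
    for stack in population:
        angle, contributing = local_incidence_angle(
            (stack.orientation_polar, stack.orientation_azimuth), illumination
        )
        wgt = np.cos(np.radians(angle)) if weighting == "cos" else 1.0
        if not contributing:
            T += wgt
            wsum += wgt
            continue
        spec = stack_reflectance(stack, optics, wl, theta=angle, polarization="unpolarized")
        R += wgt * spec.reflectance
        T += wgt * spec.transmittance
        wsum += wgt
        n_contrib += 1
    if n_contrib == 0:
        warnings.warn("all stacks are non-contributing (grazing); ensemble spectrum is zero")
    if wsum > 0:
        R /= wsum
        T /= wsum
    return ReflectanceSpectrum(wl, R, T, polarization="unpolarized")


def angular_sweep(
    population: StackPopulation,
    thetas: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    optics: OpticalConstants = OpticalConstants(),
    azimuth: float = 0.0,
    weighting: str = "cos",
) -> AngularSweepResult:
    """Ensemble peak metrics as the illumination rotates about the sample.

    Default theta grid is a full circle, 0-360 deg in 10 deg steps.
    """
    thetas = np.arange(0.0, 360.0, 10.0) if thetas is None else np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("thetas must be non-empty")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    peak_wl = np.empty_like(thetas)
    peak_amp = np.empty_like(thetas)
    for i, th in enumerate(thetas):
        spec = ensemble_reflectance(
            population, IlluminationGeometry(theta=th, azimuth=azimuth), wl, optics, weighting
        )
        pm = peak_metrics(spec)
        peak_wl[i] = pm.peak_wavelength
        peak_amp[i] = pm.peak_reflectance
    return AngularSweepResult(thetas, peak_wl, peak_amp)


def apply_thickness_noise(
    stack: StackGeometry, fraction: float, seed: int
) -> StackGeometry:
    """Multiply each platelet thickness by (1 + eps), eps ~ truncated normal.

    ``eps`` has standard deviation ``fraction / 3`` and is truncated to
    |eps| <= fraction, so every perturbed thickness stays within the
    fractional threshold of the original.  ``fraction = 0`` returns the
    stack unchanged.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return stack
    rng = np.random.default_rng(seed)
    m = len(stack.platelet_thicknesses)
    eps = rng.normal(0.0, fraction / 3.0, size=4 * m + 8)
    eps = eps[np.abs(eps) <= fraction][:m]
    while eps.size < m:  # pragma: no cover - ~0 probability refill
        extra = rng.normal(0.0, fraction / 3.0, size=4 * m)
        eps = np.concatenate([eps, extra[np.abs(extra) <= fraction]])[:m]
    new_t = tuple(t * (1.0 + e) for t, e in zip(stack.platelet_thicknesses, eps))
    return replace(stack, platelet_thicknesses=new_t)


def sample_leptokurtic_angles(
    n: int, scale: float = 10.0, tail_parameter: float = 3.0, seed: int = 0
) -> np.ndarray:
    """Heavy-tailed incidence angles centred on normal incidence (degrees).

    Draws from a Student-t distribution with ``tail_parameter`` degrees of
    freedom (excess kurtosis > 0 for df > 4 finite, infinite for df <= 4;
    leptokurtic throughout), scaled to degrees and truncated to [-45, 45].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        draw = student_t.rvs(tail_parameter, size=2 * (n - out.size) + 8, random_state=rng)
        draw = draw * scale
        out = np.concatenate([out, draw[np.abs(draw) <= 45.0]])
    return out[:n]


def design_space_map(
    thickness_grid: np.ndarray | None = None,
    spacing_grid: np.ndarray | None = None,
    n_platelets: int = 6,
    wavelengths: np.ndarray | None = None,
    angle_distribution: np.ndarray | None = None,
    noise_fraction: float = 0.0,
    seed: int = 0,
    optics: OpticalConstants = OpticalConstants(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak wavelength as a function of platelet thickness and spacing.

    For each (thickness, spacing) cell a periodic stack of ``n_platelets``
    is built; its spectrum is optionally averaged over ``angle_distribution``
    (degrees) and perturbed by fractional thickness noise.  Returns
    ``(thickness_grid, spacing_grid, peak_matrix)`` with the matrix indexed
    ``[i_thickness, j_spacing]``.  Defaults span thickness 50-90 nm and
    spacing 50-110 nm.
    """
    tg = np.arange(50.0, 90.0 + 2.5, 5.0) if thickness_grid is None else np.asarray(thickness_grid, float)
    sg = np.arange(50.0, 110.0 + 2.5, 5.0) if spacing_grid is None else np.asarray(spacing_grid, float)
    if tg.size == 0 or sg.size == 0:
        raise ValueError("grids must be non-empty")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    angles = np.array([0.0]) if angle_distribution is None else np.asarray(angle_distribution, float)
    rng = np.random.default_rng(seed)

    peaks = np.empty((tg.size, sg.size))
    for i, t in enumerate(tg):
        for j, s in enumerate(sg):
            stack = StackGeometry(
                platelet_thicknesses=(t,) * n_platelets,
                gap_thicknesses=(s,) * (n_platelets - 1),
            )
            if noise_fraction > 0:
                stack = apply_thickness_noise(
                    stack, noise_fraction, int(rng.integers(0, 2**31 - 1))
                )
            R = np.zeros_like(wl)
            for th in angles:
                spec = stack_reflectance(stack, optics, wl, theta=abs(float(th)))
                R += spec.reflectance
            R /= angles.size
            spec = ReflectanceSpectrum(wl, R, 1.0 - R)
            peaks[i, j] = peak_metrics(spec).peak_wavelength
    return tg, sg, peaks
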