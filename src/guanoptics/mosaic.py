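"""Synthetic granule-mosaic micrograph analogs and granule measurement.

Structurally colored skin appears pixelated under the microscope: discrete
color granules 0.2-16 um across on a dark (or pigmented) background.
:func:`render_mosaic` draws a seeded synthetic analog of such a micrograph —
non-overlapping disks whose diameters follow the species' granule-size
statistics and whose colors come from freshly sampled platelet-stack
spectra — together with a ground-truth table.  :func:`measure_granules`
recovers diameters from the image alone by thresholding and
connected-component analysis, mirroring how granules are measured as
optically distinct islands of a single color.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure as sk_measure

from . import colorimetry
from .structures import SpeciesPreset, get_preset, sample_stack_population
from .tmm import peak_metrics, stack_reflectance

__all__ = [
    "MosaicImage",
    "DIAMETER_RANGE_UM",
    "render_mosaic",
    "measure_granules",
]

DIAMETER_RANGE_UM = (0.2, 16.0)
_COLOR_GRID = np.arange(380.0, 780.5, 2.0)


@dataclass
class MosaicImage:
    """8-bit RGB synthetic micrograph with physical pixel pitch (um/px)."""

    pixels: np.ndarray
    pixel_pitch: float
    seed: int

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if min(self.pixels.shape[:2]) < 64:
            raise ValueError("image dimensions must be >= 64 x 64")

    def to_png(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, self.pixels)


def _sample_diameters(preset: SpeciesPreset, n: int, rng: np.random.Generator) -> np.ndarray:
    from scipy.stats import truncnorm

    lo, hi = DIAMETER_RANGE_UM
    mu, sd = preset.granule_diameter_mean, preset.granule_diameter_sd
    if sd == 0:
        return np.full(n, mu)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def render_mosaic(
    preset: SpeciesPreset | str,
    image_size: int | tuple[int, int] = 1024,
    pixel_pitch: float = 0.2,
    fill_fraction: float = 0.3,
    seed: int = 0,
    n_granules: int | None = None,
    background_rgb: tuple[int, int, int] = (0, 0, 0),
    max_attempts_per_granule: int = 2000,
    return_spectra: bool = False,
) -> tuple[MosaicImage, pd.DataFrame]:
    """Render a seeded granule mosaic plus its ground-truth table.

    Granule diameters are truncated-normal from the preset, clipped to the
    observed global range 0.2-16 um; granules are placed by dart throwing
    without overlap until ``fill_fraction`` of the field is covered (or
    ``n_granules`` are placed, if given).  Each granule is colored by the
    sRGB rendering of one freshly sampled stack's normal-incidence spectrum.
    An unreachable fill yields a partial render; the achieved fraction is
    stored in ``table.attrs["achieved_fill_fraction"]``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if fill_fraction > 0.5:
        raise ValueError("fill_fraction must be <= 0.5 for dart-throwing placement")
    h, w = (image_size, image_size) if isinstance(image_size, int) else image_size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x305A1C]))

    field_w, field_h = w * pixel_pitch, h * pixel_pitch
    field_area = field_w * field_h
    target_area = fill_fraction * field_area

    # fix the granule set first (in draw order, so sizes stay unbiased), then
    # place it largest-first, which packs far better than random order
    if n_granules is not None:
        batch = _sample_diameters(preset, n_granules, rng)
    else:
        batch_list: list[float] = []
        acc = 0.0
        while acc < target_area:
            d = float(_sample_diameters(preset, 1, rng)[0])
            batch_list.append(d)
            acc += np.pi * (d / 2.0) ** 2
        batch = np.asarray(batch_list)
    diameters = np.sort(batch)[::-1]

    centers: list[tuple[float, float]] = []
    used_d: list[float] = []
    area = 0.0
    placed_xy = np.empty((0, 2))
    placed_r = np.empty(0)
    for d in diameters:
        r = d / 2.0
        if 2 * r > min(field_w, field_h):
            continue
        for _ in range(max_attempts_per_granule):
            x = rng.uniform(r, field_w - r)
            y = rng.uniform(r, field_h - r)
            if placed_r.size:
                if np.any((placed_xy[:, 0] - x) ** 2 + (placed_xy[:, 1] - y) ** 2 < (placed_r + r) ** 2):
                    continue
            centers.append((x, y))
            used_d.append(float(d))
            placed_xy = np.vstack([placed_xy, [x, y]])
            placed_r = np.append(placed_r, r)
            area += np.pi * r**2
            break

    n = len(used_d)
    pop = sample_stack_population(preset, max(n, 1), int(rng.integers(0, 2**31 - 1)))
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:, :] = np.asarray(background_rgb, dtype=np.uint8)

    rows = []
    spectra = []
    for i in range(n):
        spec = stack_reflectance(pop.stacks[i], preset.optics, _COLOR_GRID, theta=0.0)
        if return_spectra:
            spectra.append(spec)
        chrom = colorimetry.spectrum_to_chromaticity(spec)
        pm = peak_metrics(spec)
        rgb = np.array([round(255 * c) for c in chrom.srgb], dtype=np.uint8)
        cx, cy = centers[i]
        r_px = used_d[i] / 2.0 / pixel_pitch
        cx_px, cy_px = cx / pixel_pitch, cy / pixel_pitch
        x0, x1 = max(int(cx_px - r_px) - 1, 0), min(int(cx_px + r_px) + 2, w)
        y0, y1 = max(int(cy_px - r_px) - 1, 0), min(int(cy_px + r_px) + 2, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        sel = (xx - cx_px) ** 2 + (yy - cy_px) ** 2 <= r_px**2
        img[y0:y1, x0:x1][sel] = rgb
        rows.append(
            {
                "id": i,
                "cx_um": cx,
                "cy_um": cy,
                "diameter_um": used_d[i],
                "peak_nm": pm.peak_wavelength,
                "R": int(rgb[0]),
                "G": int(rgb[1]),
                "B": int(rgb[2]),
            }
        )

    table = pd.DataFrame(
        rows, columns=["id", "cx_um", "cy_um", "diameter_um", "peak_nm", "R", "G", "B"]
    )
    table.attrs["achieved_fill_fraction"] = area / field_area
    table.attrs["preset"] = preset.name
    if return_spectra:
        table.attrs["spectra"] = spectra
    return MosaicImage(img, pixel_pitch, int(seed)), table


def measure_granules(
    image: MosaicImage, background_threshold: float = 10.0
) -> np.ndarray:
    """Granule equivalent-circle diameters (um) from the image alone.

    Foreground is any pixel whose maximum channel exceeds the threshold;
    granules are 8-connected components; diameter is sqrt(4 A / pi) scaled
    by the pixel pitch.  Components touching the image border are excluded.
    Returns an empty array (with a warning) when no foreground exists.
    """
    import warnings

    fg = image.pixels.max(axis=2) > background_threshold
    if not fg.any():
        warnings.warn("no foreground pixels above threshold")
        return np.empty(0)
    labels = sk_measure.label(fg, connectivity=2)
    h, w = labels.shape
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    diameters = []
    for prop in sk_measure.regionprops(labels):
        if prop.label in border:
            continue
        diameters.append(prop.equivalent_diameter_area * image.pixel_pitch)
    return np.asarray(diameters)
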