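"""Species presets and stochastic generation of platelet-stack populations.

The measured ultrastructure of each species is summarized by a
:class:`SpeciesPreset` (platelet thickness, inter-platelet gap, platelets per
stack, stack orientation, granule diameter).  :func:`sample_stack_population`
draws seeded populations of :class:`~guanoptics.tmm.StackGeometry` from those
summaries; :func:`voxelize_population` rasterizes a population onto a voxel
grid the way a focused-ion-beam serial-section volume samples real tissue,
and :func:`measure_population` recovers the structural statistics from the
voxel data alone, closing the generate/measure loop.

Distribution choices: thickness and gap are truncated normal (summaries give
mean +/- sd and at most a range); platelet counts are a discretized normal
clipped to [1, platelets_max]; azimuths are uniform on [0, 360).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import ndimage
from scipy.stats import truncnorm

from .tmm import OpticalConstants, StackGeometry

__all__ = [
    "SpeciesPreset",
    "StackPopulation",
    "LabeledVolume",
    "MeasuredStatistics",
    "PlacementError",
    "UnknownPresetError",
    "get_preset",
    "list_presets",
    "sample_stack_population",
    "voxelize_population",
    "measure_population",
]

_ORIENTATION_MODELS = ("uniform_0_90", "normal_mean_sd")


class UnknownPresetError(KeyError):
    pass


class PlacementError(RuntimeError):
    """Raised when stacks cannot be placed without overlap."""


@dataclass(frozen=True)
class SpeciesPreset:
    """Printed structural statistics for one species.

    Lengths in nm except granule diameters and in-plane extents (um).
    ``assumptions`` names fields whose values are package choices rather
    than measured numbers.
    """

    name: str
    thickness_mean: float
    thickness_sd: float
    gap_mean: float
    gap_sd: float
    platelets_mean: float
    platelets_sd: float
    platelets_max: int
    orientation_model: str
    orientation_mean: float
    orientation_sd: float
    granule_diameter_mean: float
    granule_diameter_sd: float
    thickness_range: tuple[float, float] | None = None
    gap_min: float = 0.0
    inplane_length_um: tuple[float, float] = (0.1, 2.0)
    inplane_width_um: tuple[float, float] = (0.1, 0.5)
    optics: OpticalConstants = field(default_factory=OpticalConstants)
    assumptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "thickness_mean",
            "gap_mean",
            "platelets_mean",
            "granule_diameter_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "thickness_sd",
            "gap_sd",
            "platelets_sd",
            "orientation_sd",
            "granule_diameter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.platelets_max < 1:
            raise ValueError("platelets_max must be >= 1")
        if self.orientation_model not in _ORIENTATION_MODELS:
            raise ValueError(f"orientation_model must be one of {_ORIENTATION_MODELS}")

    @property
    def mean_pitch(self) -> float:
        """Mean multilayer periodicity: platelet thickness + gap (nm)."""
        return self.thickness_mean + self.gap_mean


def _load_preset_table() -> dict:
    text = (
        importlib.resources.files("guanoptics").joinpath("presets.yaml").read_text()
    )
    return yaml.safe_load(text)


_PRESET_CACHE: dict[str, SpeciesPreset] | None = None


def _presets() -> dict[str, SpeciesPreset]:
    global _PRESET_CACHE
    if _PRESET_CACHE is None:
        table = _load_preset_table()
        out = {}
        for key, row in table.items():
            row = dict(row)
            rng = row.pop("thickness_range", None)
            out[key] = SpeciesPreset(
                thickness_range=tuple(rng) if rng else None,
                inplane_length_um=tuple(row.pop("inplane_length_um")),
                inplane_width_um=tuple(row.pop("inplane_width_um")),
                assumptions=tuple(row.pop("assumptions", ())),
                **row,
            )
        _PRESET_CACHE = out
    return _PRESET_CACHE


def list_presets() -> list[str]:
    return sorted(_presets())


def get_preset(name: str) -> SpeciesPreset:
    """Look up a species preset by key (e.g. ``"c_annae"``)."""
    try:
        return _presets()[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; known presets: {', '.join(list_presets())}"
        ) from None


@dataclass
class StackPopulation:
    """A seeded sample of platelet stacks drawn from one preset."""

    stacks: list[StackGeometry]
    preset_name: str
    seed: int

    def __len__(self) -> int:
        return len(self.stacks)

    def __iter__(self):
        return iter(self.stacks)

    def to_json(self, path) -> None:
        payload = {
            "preset_name": self.preset_name,
            "seed": self.seed,
            "stacks": [
                {
                    "platelet_thicknesses": list(s.platelet_thicknesses),
                    "gap_thicknesses": list(s.gap_thicknesses),
                    "orientation_polar": s.orientation_polar,
                    "orientation_azimuth": s.orientation_azimuth,
                }
                for s in self.stacks
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "StackPopulation":
        payload = json.loads(Path(path).read_text())
        stacks = [StackGeometry(**row) for row in payload["stacks"]]
        return cls(stacks, payload["preset_name"], payload["seed"])


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_stack_population(
    preset: SpeciesPreset | str, n_stacks: int, seed: int
) -> StackPopulation:
    """Draw a seeded population of stacks from a species preset.

    Thicknesses are truncated-normal within the preset's printed range (or
    simply positive when no range is printed); gaps are truncated-normal
    above ``gap_min``; platelet counts are a rounded normal clipped to
    [1, platelets_max]; polar orientations follow the preset's orientation
    model and azimuths are uniform.  Identical (preset, n, seed) gives an
    identical population.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    rng = np.random.default_rng(seed)

    counts = np.rint(rng.normal(preset.platelets_mean, preset.platelets_sd, n_stacks))
    counts = np.clip(counts, 1, preset.platelets_max).astype(int)

    t_lo, t_hi = preset.thickness_range or (0.0, np.inf)
    g_lo = max(preset.gap_min, 0.0)

    if preset.orientation_model == "uniform_0_90":
        polar = rng.uniform(0.0, 90.0, n_stacks)
    else:
        polar = _truncnorm_rvs(
            preset.orientation_mean, preset.orientation_sd, 0.0, 90.0, n_stacks, rng
        )
    azimuth = rng.uniform(0.0, 360.0, n_stacks)

    stacks = []
    for i, m in enumerate(counts):
        thick = _truncnorm_rvs(preset.thickness_mean, preset.thickness_sd, t_lo, t_hi, m, rng)
        gaps = _truncnorm_rvs(preset.gap_mean, preset.gap_sd, g_lo, np.inf, max(m - 1, 0), rng)
        stacks.append(
            StackGeometry(
                platelet_thicknesses=tuple(thick),
                gap_thicknesses=tuple(gaps),
                orientation_polar=float(polar[i]),
                orientation_azimuth=float(azimuth[i]),
            )
        )
    name = preset.name
    return StackPopulation(stacks=stacks, preset_name=name, seed=int(seed))


# --------------------------------------------------------------------------
# Voxelization and measurement


def _orientation_axes(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Orthonormal frame (u = stack normal, v, w in-plane) as rows."""
    p = np.radians(polar_deg)
    a = np.radians(azimuth_deg)
    u = np.array([np.sin(p) * np.cos(a), np.sin(p) * np.sin(a), np.cos(p)])
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.vstack([u, v, w])


@dataclass
class _StackChunk:
    label: int
    origin_nm: np.ndarray  # world position of voxel (0,0,0) corner
    mask: np.ndarray  # bool, (nx, ny, nz)


@dataclass
class LabeledVolume:
    """Labeled voxel occupancy of a stack population.

    Stored as per-stack boolean sub-volumes with world-space origins (a
    chunked representation of one large, mostly empty labeled volume).
    """

    voxel_size: float
    chunks: list[_StackChunk]
    bounds_nm: np.ndarray  # (2, 3) world min/max of the enclosing box
    clipped_labels: tuple[int, ...] = ()

    @property
    def n_stacks(self) -> int:
        return len(self.chunks)

    def occupied_voxels(self) -> int:
        return int(sum(c.mask.sum() for c in self.chunks))

    def to_dense(self, max_voxels: int = int(2e8)) -> np.ndarray:
        """Materialize a single labeled uint16 array (small volumes only)."""
        lo, hi = self.bounds_nm
        shape = np.ceil((hi - lo) / self.voxel_size).astype(int) + 1
        if int(np.prod(shape)) > max_voxels:
            raise MemoryError("dense volume would exceed max_voxels")
        dense = np.zeros(shape, dtype=np.uint16)
        for c in self.chunks:
            off = np.rint((c.origin_nm - lo) / self.voxel_size).astype(int)
            sl = tuple(slice(o, o + s) for o, s in zip(off, c.mask.shape))
            dense[sl][c.mask] = c.label
        return dense

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.to_dense().transpose(2, 0, 1))


def _stack_extent(stack: StackGeometry) -> float:
    return float(sum(stack.platelet_thicknesses) + sum(stack.gap_thicknesses))


def _rasterize_stack(
    stack: StackGeometry, center_nm: np.ndarray, radius_nm: float, voxel: float
) -> _StackChunk:
    axes = _orientation_axes(stack.orientation_polar, stack.orientation_azimuth)
    u = axes[0]
    length = _stack_extent(stack)
    half = 0.5 * length * np.abs(u) + radius_nm * np.sqrt(np.clip(1 - u**2, 0, None))
    half += 2 * voxel
    lo = center_nm - half
    n_vox = np.ceil(2 * half / voxel).astype(int)
    coords = [
        (lo[k] + (np.arange(n_vox[k], dtype=np.float32) + 0.5) * voxel) - center_nm[k]
        for k in range(3)
    ]
    X = coords[0][:, None, None]
    Y = coords[1][None, :, None]
    Z = coords[2][None, None, :]
    s = u[0] * X + u[1] * Y + u[2] * Z  # axial coordinate, 0 at stack center
    r2 = (X**2 + Y**2 + Z**2) - s**2
    lateral = r2 <= radius_nm**2
    mask = np.zeros(tuple(n_vox), dtype=bool)
    z = -0.5 * length
    for i, t in enumerate(stack.platelet_thicknesses):
        mask |= (s >= z) & (s < z + t) & lateral
        z += t
        if i < len(stack.gap_thicknesses):
            z += stack.gap_thicknesses[i]
    # crop to the tight occupied bounding box
    occ = np.argwhere(mask)
    if occ.size == 0:
        return _StackChunk(0, lo, np.zeros((1, 1, 1), dtype=bool))
    mn = occ.min(axis=0)
    mx = occ.max(axis=0) + 1
    sub = mask[mn[0] : mx[0], mn[1] : mx[1], mn[2] : mx[2]]
    return _StackChunk(0, lo + mn * voxel, np.ascontiguousarray(sub))


def voxelize_population(
    population: StackPopulation,
    voxel_size: float = 5.0,
    platelet_radius_nm: float = 100.0,
    fill_target: float = 0.05,
    max_attempts_per_stack: int = 1000,
) -> LabeledVolume:
    """Rasterize a population into a labeled voxel volume.

    Stacks are placed by seeded dart throwing with non-overlapping bounding
    spheres inside a cube sized so spheres occupy ``fill_target`` of it; each
    platelet becomes a disk of ``platelet_radius_nm`` and its own thickness,
    normal to the stack orientation.  Raises :class:`PlacementError` when a
    stack cannot be placed within ``max_attempts_per_stack`` tries.
    """
    if voxel_size > 10.0:
        raise ValueError("voxel_size must be <= 10 nm for meaningful recovery")
    rng = np.random.default_rng(np.random.SeedSequence([population.seed, 0x7C6E]))
    stacks = population.stacks
    radii = np.array(
        [
            np.hypot(0.5 * _stack_extent(s), platelet_radius_nm) + voxel_size
            for s in stacks
        ]
    )
    sphere_vol = (4.0 / 3.0) * np.pi * (radii**3).sum()
    side = (sphere_vol / max(fill_target, 1e-6)) ** (1.0 / 3.0)
    order = np.argsort(-radii)  # biggest first

    centers = np.full((len(stacks), 3), np.nan)
    placed_idx: list[int] = []
    for i in order:
        r = radii[i]
        for _ in range(max_attempts_per_stack):
            c = rng.uniform(r, side - r, size=3)
            if placed_idx:
                prev = centers[placed_idx]
                if np.any(
                    np.sum((prev - c) ** 2, axis=1) < (radii[placed_idx] + r) ** 2
                ):
                    continue
            centers[i] = c
            placed_idx.append(i)
            break
        else:
            raise PlacementError(
                f"could not place stack {i} after {max_attempts_per_stack} attempts; "
                "reduce fill_target or population size"
            )

    chunks = []
    for i, stack in enumerate(stacks):
        chunk = _rasterize_stack(stack, centers[i], platelet_radius_nm, voxel_size)
        chunk.label = i + 1
        chunks.append(chunk)
    bounds = np.array([[0.0, 0.0, 0.0], [side, side, side]])
    return LabeledVolume(voxel_size=voxel_size, chunks=chunks, bounds_nm=bounds)


@dataclass
class MeasuredStatistics:
    """Structural statistics recovered from a labeled voxel volume."""

    thickness_mean: float
    thickness_sd: float
    gap_mean: float
    gap_sd: float
    platelet_count_mean: float
    orientation_mean: float
    n_stacks_measured: int
    n_stacks_excluded: int

    def to_dict(self) -> dict:
        return asdict(self)


def _measure_chunk(mask: np.ndarray, voxel: float):
    """Per-stack measurement: platelet thicknesses, gaps, count, normal polar angle."""
    labels, n_plates = ndimage.label(mask)
    if n_plates == 0:
        return None
    coords_all = []
    normals = []
    for k in range(1, n_plates + 1):
        pts = np.argwhere(labels == k).astype(float) * voxel
        coords_all.append(pts)
        if len(pts) >= 4:
            cov = np.cov((pts - pts.mean(axis=0)).T)
            evals, evecs = np.linalg.eigh(cov)
            normals.append(evecs[:, 0])  # smallest-variance axis = plate normal
    if not normals:
        return None
    ref = normals[0]
    normals = [n if np.dot(n, ref) >= 0 else -n for n in normals]
    normal = np.mean(normals, axis=0)
    normal /= np.linalg.norm(normal)

    centroids = np.array([p.mean(axis=0) for p in coords_all])
    proj_c = centroids @ normal
    order = np.argsort(proj_c)

    # in-plane orthonormal basis shared by all plates of the stack
    helper = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    plane = np.column_stack([e1, e2])

    thicknesses = []
    for k in order:
        pts = coords_all[k]
        # project voxels into footprint cells; interior columns hold t/voxel
        # voxels each, so thickness = voxel * mean count over full columns
        # (partially covered rim columns are rejected against the median)
        inplane = pts @ plane
        cells, counts = np.unique(
            np.rint(inplane / voxel).astype(int), axis=0, return_counts=True
        )
        med = np.median(counts)
        full = counts[counts > 0.5 * med]
        thicknesses.append(voxel * float(np.mean(full)))
    gaps = []
    for j in range(len(order) - 1):
        d = proj_c[order[j + 1]] - proj_c[order[j]]
        gaps.append(d - 0.5 * (thicknesses[j] + thicknesses[j + 1]))
    polar = np.degrees(np.arccos(np.clip(abs(normal[2]), 0, 1)))
    return thicknesses, gaps, n_plates, polar


def measure_population(volume: LabeledVolume, voxel_size: float | None = None) -> MeasuredStatistics:
    """Recover thickness/gap/count/orientation statistics from voxel data.

    Plate normals are estimated per platelet from the principal axes of the
    occupied voxels; thickness is occupied volume divided by the plate
    footprint area; gaps are centroid separations along the stack normal
    minus the half-thicknesses of the flanking plates.  Stacks clipped by
    the volume boundary are excluded and counted.
    """
    voxel = volume.voxel_size if voxel_size is None else voxel_size
    thicknesses: list[float] = []
    gaps: list[float] = []
    counts: list[int] = []
    polars: list[float] = []
    excluded = 0
    clipped = set(volume.clipped_labels)
    for chunk in volume.chunks:
        if chunk.label in clipped:
            excluded += 1
            continue
        res = _measure_chunk(chunk.mask, voxel)
        if res is None:
            excluded += 1
            continue
        t, g, n, p = res
        thicknesses.extend(t)
        gaps.extend(g)
        counts.append(n)
        polars.append(p)
    if not counts:
        raise ValueError("no measurable stacks in volume")
    return MeasuredStatistics(
        thickness_mean=float(np.mean(thicknesses)),
        thickness_sd=float(np.std(thicknesses, ddof=1)) if len(thicknesses) > 1 else 0.0,
        gap_mean=float(np.mean(gaps)) if gaps else float("nan"),
        gap_sd=float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0,
        platelet_count_mean=float(np.mean(counts)),
        orientation_mean=float(np.mean(polars)),
        n_stacks_measured=len(counts),
        n_stacks_excluded=excluded,
    )
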