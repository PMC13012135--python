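# Methods

## The physical model

Structurally colored nudibranch skin contains micron-scale granules
("pixels"), each built from stacks of crystalline guanine platelets
(refractive index n_H = 1.83 in-plane) separated by cytoplasmic gaps
(n_L = 1.34, shared with the surrounding tissue). Each stack is a finite
Bragg reflector: at normal incidence the first-order reflectance maximum
sits near

    lambda = 2 (n_H d_H cos(theta_H) + n_L d_L cos(theta_L))

and blue-shifts with incidence angle. The package models this chain in four
stages:

1. **Single stack (`tmm`).** The characteristic-matrix transfer-matrix
   method gives the exact plane-wave reflectance/transmittance of a stack
   of homogeneous, lossless, non-dispersive layers, for s, p, or
   unpolarized light (arithmetic mean of s and p intensities), bounded by
   tissue on both sides. Indices are real scalars: dispersion and guanine
   birefringence are collapsed to the single in-plane value 1.83, gaps and
   ambient share 1.34. For the mean-geometry stack (6 platelets of 53 nm,
   5 gaps of 70 nm) this predicts a peak at 382 nm with reflectance 0.91
   and FWHM about 111 nm — a bright violet-blue mirror from only six
   crystals, which is the point of using guanine.

2. **Populations (`structures`).** Species presets hold the measured
   summary statistics (mean, sd, range where reported). Sampling uses
   truncated normals for platelet thickness (within the reported range, or
   positive) and gaps (positive; a 5 nm floor for *B. stephanieae*, whose
   spacing is reported only as poorly defined), a rounded normal clipped to
   [1, max] for platelet counts, the preset's orientation model for polar
   angles (uniform on [0, 90] degrees by default for *C. annae*; the
   normal(50, 30) summary model is available), and uniform azimuths. All
   randomness flows through one `numpy` Generator per call, so identical
   seeds give byte-identical populations.

3. **Orientation ensemble (`ensemble`).** Tissue reflectance is the
   intensity average over stacks, each evaluated at its *local* incidence
   angle — the angle between the illumination direction and the stack
   normal. Normals are treated as unsigned axes, because a dielectric
   multilayer in a symmetric ambient reflects identically from either face;
   the local angle therefore folds into [0, 90] degrees, full-circle
   illumination sweeps are meaningful, and only the degenerate grazing case
   (>= 89.9 degrees) is excluded. Stacks are weighted by the geometric
   cross-section they present to the beam (cos of the local angle),
   an energy-based weight: a plate tilted nearly parallel
   to the beam intercepts almost no light, and weighting it equally lets
   near-grazing broadband Fresnel reflection swamp the average and drag the
   ensemble peak to the short-wavelength edge of the grid. With the cosine
   weight the 100-stack uniform-orientation ensemble peaks at 382 nm at
   normal illumination and stays below 430 nm at every angle of a 0-360
   degree sweep — the matte, angle-independent blue. An `"equal"` weighting
   mode is kept for comparison.

4. **Color (`colorimetry`, `mosaic`).** Spectra are integrated to CIE 1931
   XYZ under D65 (2-degree observer; tables embedded at 10 nm and linearly
   interpolated — adequate for broadband reflectances, and verified against
   the canonical white point to better than 0.001 in (x, y)), then rendered
   to sRGB with channel clipping and an out-of-gamut flag. Macroscopic hue
   is the weighted mean of pixel spectra (`mix_pixel_spectra`); a spread of
   equal-amplitude peaks across the visible mixes to within 0.05 of the
   white point, which is the proposed mechanism for white body regions.
   The 0.05 white-distance threshold is a package convention, not a
   measured boundary. Synthetic mosaics draw granules as non-overlapping
   disks (truncated-normal diameters clipped to the observed 0.2-16 um
   range), each colored by a freshly sampled stack's normal-incidence
   spectrum; measurement recovers equivalent-circle diameters by
   thresholding and 8-connected component analysis, excluding
   border-touching components.

## Voxelize-and-measure recovery

`voxelize_population` emulates a serial-section voxel dataset: stacks are
placed by seeded dart throwing (non-overlapping bounding spheres, packing
fraction 5%, largest first) and each platelet is rasterized as a disk of
100 nm radius and its own thickness, normal to the stack orientation, on a
5 nm grid (finer grids allowed, coarser than 10 nm rejected). The volume is
stored as per-stack sub-volumes with world-space origins — a chunked
labeled volume that keeps 200-stack populations in tens of MB where a dense
array would need gigabytes; `to_dense()` materializes small volumes.

`measure_population` uses only the voxel data: platelets are connected
components within a stack label; each plate's normal is the
smallest-variance principal axis of its voxel coordinates, and the stack
normal is their sign-aligned mean. Thickness is estimated per plate by
projecting voxels into footprint columns along the normal: an interior
column holds thickness/voxel voxels in expectation, so thickness is the
voxel size times the mean count over full columns, with partially covered
rim columns rejected against the median count. Gaps are centroid
separations along the normal minus the flanking half-thicknesses;
orientation is the angle between the stack normal and the volume axis.
On 200-stack populations this recovers the 53 nm mean thickness within
about 0.5 nm (tolerance 2 nm); the dominant residual is voxelization noise
on individual thin plates.

## Problem sizes and defaults

- Wavelength grid: 300-800 nm at 1 nm (near-UV through red); angular work
  that probes large blue shifts extends to 250 nm.
- Angular sweeps: 0-360 degrees in 10-degree steps; populations of 100
  stacks for ensemble statistics, 200 for voxel recovery; 10^4 draws for
  moment checks.
- Leptokurtic incidence angles: truncated Student-t, 3 degrees of freedom,
  10-degree scale, truncated to [-45, 45] — the family is a package choice
  pinned only by the qualitative property (symmetric, centred on normal
  incidence, heavy-tailed), and is configurable.
- Thickness noise: multiplicative, truncated Gaussian, sd = fraction/3,
  hard-capped at the fraction (default use is 10%).
- Mosaics: 0.2 um/pixel, fill fraction <= 0.5 (dart-throwing feasibility);
  granules are ideal circles, so the equivalent-circle diameter is the
  common contract between renderer and measurement.

## What the synthetic data does and does not emulate

The generator reproduces the *summary statistics* of the measured
ultrastructure — truncated-normal thicknesses and gaps, discrete platelet
counts, the orientation spread, granule-diameter distributions — but not
features those summaries do not constrain: correlations between thickness
and gap within a stack, spatial clustering of similar stacks, irregular
(faceted, non-circular) plate and granule shapes, membranes and envelopes,
or the diffuse scattering layer some species add beneath the granules.
Passing tests therefore show that the optical chain behaves correctly for
populations *consistent with the printed statistics*, not that real tissue
contains no further structure. Species for which only granule diameters
were printed (*H. tryoni*, *C. willani*, *S. neapolitana*) borrow the
*C. annae* stack statistics, flagged in the preset's `assumptions` field.

Equally, the equal-/cosine-weighted incoherent stack average is a surrogate
for full-wave simulation of a segmented volume: it omits coherent
inter-stack interference, multiple scattering, finite-plate diffraction and
collection-geometry effects, so ensemble amplitudes are comparable only as
fractions of incident intensity, and the measured 17-34% whole-volume
amplitude range is not used as a pass/fail target.

## Numerical conventions

- Degrees at every public interface; radians internal.
- Peak ties break to the lowest wavelength; FWHM uses linear interpolation
  of the half-height crossings nearest the peak and is `None` when a
  crossing is missing on either side; an all-zero spectrum returns an
  undefined-peak flag rather than raising.
- Energy conservation R + T = 1 holds to 1e-9 (machine precision in
  practice) for the lossless media used throughout.
- Refraction past the critical angle raises an explicit evanescent-wave
  error rather than silently returning complex angles (unreachable with
  the default indices, where the ambient is the lowest index).
- A single global seed expands into per-stage substreams via
  `SeedSequence([seed, stage])`, so adding a stage never perturbs the
  randomness of earlier ones.

## Known limitations

- No absorption, dispersion, or birefringence; no FDTD-class full-wave
  solver. The transfer-matrix model treats each stack as laterally
  infinite, which overestimates the reflectance of plates whose lateral
  extent (0.1-2 um) is only a few times the wavelength.
- The voxel pipeline places stacks without contact or clipping; real
  section data requires segmentation, handled upstream of this package.
- Colorimetry stops at the 380 nm observer edge: near-UV peaks (common
  here) contribute nothing to XYZ, and predator visual systems are out of
  scope.
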