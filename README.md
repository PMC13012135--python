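# guanoptics

Optical modelling of the matte, pixelated structural color of nudibranch
sea slugs — and of any tissue that colors itself with disordered stacks of
guanine platelets.

Several nudibranch species produce vivid, angle-independent blues, whites
and pastels without relying on pigment alone. The mechanism is hierarchical:
crystalline guanine platelets (refractive index n_H = 1.83) separated by
cytoplasm gaps (n_L = 1.34) form few-layer Bragg reflectors; each
micron-scale granule ("pixel") contains stacks of one tuning and reflects
one hue; stack orientations are spread broadly, so some stack always faces
the viewer and the hue does not shift with angle; and the macroscopic color
is the intensity-averaged mixture of many pixels, the way an RGB display
mixes sub-pixels. `guanoptics` implements this chain end to end:

- **`guanoptics.tmm`** — exact transfer-matrix reflectance/transmittance of
  a finite multilayer stack, Bragg-law predictions
  (lambda = 2 n d cos(theta)), and peak metrics (position, height, FWHM).
- **`guanoptics.structures`** — species presets of the measured platelet
  statistics, seeded stochastic stack populations, and a
  voxelize-and-measure pipeline that recovers those statistics from
  rasterized volumes alone.
- **`guanoptics.ensemble`** — local incidence geometry, orientation-ensemble
  spectra, full-circle angular sweeps, thickness noise, leptokurtic
  incidence-angle sampling, and the platelet-thickness x spacing
  design-space map.
- **`guanoptics.colorimetry`** — CIE 1931 tristimulus integration under D65,
  sRGB rendering, pixel color mixing, chromatic distance to white.
- **`guanoptics.mosaic`** — synthetic granule-mosaic micrograph analogs with
  ground truth, and granule-diameter measurement by connected components.
- **`guanoptics.cli`** — the `guanoptics` command with reproducible,
  config-logging subcommands (`simulate-stack`, `sweep-angle`, `design-map`,
  `render-mosaic`, `measure-mosaic`, `mix-color`, `reproduce-fig3`,
  `reproduce-s8c`).

See `docs/methods.md` for the model, its assumptions, and its limits.

## Worked example

The mean *Chromodoris annae* stack — six 53 nm platelets separated by
70 nm gaps — is already a bright violet-blue mirror, and tilting it shows
the iridescence that orientation disorder later hides:

```sh
guanoptics simulate-stack --preset c_annae --theta 0 --theta 45 --wl-min 250
```

```
INFO guanoptics: c_annae theta=0: peak 382.0 nm, R=0.909
INFO guanoptics: c_annae theta=45: peak 299.0 nm, R=0.683
```

At normal incidence the stack reflects 91% of the light at its 382 nm
peak (the Bragg prediction 2 x 1.551 x 123 nm = 381.6 nm, using the
thickness-weighted mean index); at 45 degrees the peak has blue-shifted by
more than 80 nm. Averaging a 100-stack population with orientations spread
uniformly over 0-90 degrees removes that shift:

```python
import numpy as np
from guanoptics import sample_stack_population, angular_sweep

pop = sample_stack_population("c_annae", 100, seed=42)
sweep = angular_sweep(pop, np.arange(0, 360, 10))
print(sweep.peak_wavelengths.max())   # 382.0 — never redder than 430 nm
```

The ensemble peak stays at 382 nm at normal illumination and never moves
past 430 nm at any angle of the full-circle sweep: matte blue from an
intrinsically iridescent reflector.

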