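# Species structural statistics for guanine platelet stacks and color granules.
# Thicknesses/gaps in nm, granule diameters in um, angles in degrees.
# `assumptions` lists fields that are package choices, not measured values.

c_annae:
  name: "C. annae"
  thickness_mean: 53.0
  thickness_sd: 10.0
  thickness_range: [39.0, 68.0]
  gap_mean: 70.0
  gap_sd: 24.0
  platelets_mean: 6.0
  platelets_sd: 3.0
  platelets_max: 16
  orientation_model: uniform_0_90
  orientation_mean: 50.0
  orientation_sd: 30.0
  granule_diameter_mean: 3.0
  granule_diameter_sd: 3.0
  inplane_length_um: [0.1, 2.0]
  inplane_width_um: [0.1, 0.5]
  assumptions: []

h_bullockii:
  name: "H. bullockii"
  thickness_mean: 49.0
  thickness_sd: 7.0
  thickness_range: null
  gap_mean: 69.0
  gap_sd: 20.0
  platelets_mean: 6.0
  platelets_sd: 2.0
  platelets_max: 10
  orientation_model: uniform_0_90
  orientation_mean: 50.0
  orientation_sd: 30.0
  granule_diameter_mean: 7.0
  granule_diameter_sd: 4.0
  inplane_length_um: [0.1, 2.0]
  inplane_width_um: [0.1, 0.5]
  assumptions: [platelets_mean, platelets_sd, orientation_model]

b_stephanieae:
  name: "B. stephanieae"
  thickness_mean: 150.0
  thickness_sd: 30.0
  thickness_range: null
  # spacing between platelets is poorly defined and far smaller than in the
  # dorid species relative to plate thickness; modelled as a narrow gap
  gap_mean: 20.0
  gap_sd: 10.0
  gap_min: 5.0
  platelets_mean: 6.0
  platelets_sd: 3.0
  platelets_max: 16
  orientation_model: uniform_0_90
  orientation_mean: 50.0
  orientation_sd: 30.0
  granule_diameter_mean: 8.0
  granule_diameter_sd: 4.0
  inplane_length_um: [0.1, 2.0]
  inplane_width_um: [0.1, 0.5]
  assumptions: [gap_mean, gap_sd, gap_min, platelets_mean, platelets_sd, orientation_model]

h_tryoni:
  name: "H. tryoni"
  thickness_mean: 53.0
  thickness_sd: 10.0
  thickness_range: null
  gap_mean: 70.0
  gap_sd: 24.0
  platelets_mean: 6.0
  platelets_sd: 3.0
  platelets_max: 16
  orientation_model: uniform_0_90
  orientation_mean: 50.0
  orientation_sd: 30.0
  granule_diameter_mean: 3.0
  granule_diameter_sd: 2.0
  inplane_length_um: [0.1, 2.0]
  inplane_width_um: [0.1, 0.5]
  assumptions: [thickness_mean, thickness_sd, gap_mean, gap_sd, platelets_mean, platelets_sd]

c_willani:
  name: "C. willani"
  thickness_mean: 53.0
  thickness_sd: 10.0
  thickness_range: null
  gap_mean: 70.0
  gap_sd: 24.0
  platelets_mean: 6.0
  platelets_sd: 3.0
  platelets_max: 16
  orientation_model: uniform_0_90
  orientation_mean: 50.0
  orientation_sd: 30.0
  granule_diameter_mean: 1.0
  granule_diameter_sd: 0.7
  inplane_length_um: [0.1, 2.0]
  inplane_width_um: [0.1, 0.5]
  assumptions: [thickness_mean, thickness_sd, gap_mean, gap_sd, platelets_mean, platelets_sd]

s_neapolitana:
  name: "S. neapolitana"
  thickness_mean: 53.0
  thickness_sd: 10.0
  thickness_range: null
  gap_mean: 70.0
  gap_sd: 24.0
  platelets_mean: 6.0
  platelets_sd: 3.0
  platelets_max: 16
  orientation_model: uniform_0_90
  orientation_mean: 50.0
  orientation_sd: 30.0
  granule_diameter_mean: 5.0
  granule_diameter_sd: 2.0
  inplane_length_um: [0.1, 2.0]
  inplane_width_um: [0.1, 0.5]
  assumptions: [thickness_mean, thickness_sd, gap_mean, gap_sd, platelets_mean, platelets_sd]

# Idealized 10-platelet periodic stack used by the incidence-angle sweep and
# design-space recipes (55 nm platelets, 70 nm gaps, no dispersion in counts).
s8_n10:
  name: "S8 idealized N=10"
  thickness_mean: 55.0
  thickness_sd: 0.0
  thickness_range: null
  gap_mean: 70.0
  gap_sd: 0.0
  platelets_mean: 10.0
  platelets_sd: 0.0
  platelets_max: 10
  orientation_model: uniform_0_90
  orientation_mean: 50.0
  orientation_sd: 30.0
  granule_diameter_mean: 3.0
  granule_diameter_sd: 3.0
  inplane_length_um: [0.1, 2.0]
  inplane_width_um: [0.1, 0.5]
  assumptions: [granule_diameter_mean, granule_diameter_sd]
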