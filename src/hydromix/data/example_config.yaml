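# Example run configuration: bench-scale stirred hydrolysis of pretreated
# spruce slurry.  All blocks are optional; omitted values fall back to the
# documented, anchor-calibrated defaults.
seed: 1

geometry:
  tank_diameter_m: 0.130
  impeller_diameter_m: 0.070
  blade_width_m: 0.020
  working_volume_m3: 9.8e-4
  fluid_density_kg_m3: 1000.0

# Leaving the rheology block empty selects the package default: n_pl = 0.5,
# K_s = 11.5, prefactor a pinned to the 2.0 Pa s (12% WIS, 50 1/s) anchor and
# WIS exponent b solved so the reference run averages 1.5 kW/m3.
rheology: {}

correlation:
  k1: 346.7
  k2: 1.27

composition:
  wis0_pct: 13.0
  glucan_frac_of_wis: 0.48
  initial_liquid_glucose_g_l: 29.8
  dilute_to_wis_pct: 10.0

conditions:
  - {speed_rpm: 25,  enzyme_load_fpu_per_g: 20}
  - {speed_rpm: 75,  enzyme_load_fpu_per_g: 20}
  - {speed_rpm: 150, enzyme_load_fpu_per_g: 20}
  - {speed_rpm: 300, enzyme_load_fpu_per_g: 20}
  - {speed_rpm: 500, enzyme_load_fpu_per_g: 20}
  - {speed_rpm: 25,  enzyme_load_fpu_per_g: 10}
  - {speed_rpm: 75,  enzyme_load_fpu_per_g: 10}
  - {speed_rpm: 150, enzyme_load_fpu_per_g: 10}
  - {speed_rpm: 300, enzyme_load_fpu_per_g: 10}
  - {speed_rpm: 500, enzyme_load_fpu_per_g: 10}

grid:
  duration_h: 96.0
  step_h: 0.5

noise:
  glucose_cv: 0.04
  power_cv: 0.05
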