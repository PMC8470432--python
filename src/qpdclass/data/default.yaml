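# Default study configuration: a 6-class bead-identification problem on a
# single-beam optical trap with quadrant-photodetector readout.
# 6 acquisitions per class, 120 s each at 10 kHz, cut into 500 ms segments.
#
# Units are spelled out in every key.  The per-class trap stiffnesses and the
# detector transfer model are simulation conventions (no published values
# exist for them); see docs/methods.md for how the defaults were chosen.

classes:
  - {label: ps3,   material: PS,   diameter_um: 3.0, refractive_index: 1.5731}
  - {label: ps4,   material: PS,   diameter_um: 4.0, refractive_index: 1.5731}
  - {label: ps8,   material: PS,   diameter_um: 8.0, refractive_index: 1.5731}
  - {label: pmma3, material: PMMA, diameter_um: 3.0, refractive_index: 1.4824}
  - {label: pmma8, material: PMMA, diameter_um: 8.0, refractive_index: 1.4824}
  - {label: none,  material: NONE, diameter_um: 0.0, refractive_index: 1.0}

signals_per_class: 6

# Per-class trap stiffness (x, y, z) in N/m.  Transverse stiffness grows
# with index contrast (PS > PMMA) and falls for beads larger than the focal
# spot; axial stiffness is 0.2x transverse.
stiffness_table_N_per_m:
  ps3:   [5.0e-6, 5.0e-6, 1.0e-6]
  ps4:   [4.5e-6, 4.5e-6, 0.9e-6]
  ps8:   [4.0e-6, 4.0e-6, 0.8e-6]
  pmma3: [3.5e-6, 3.5e-6, 0.7e-6]
  pmma8: [1.6e-6, 1.6e-6, 0.32e-6]
  none:  [0.0, 0.0, 0.0]

medium:
  temperature_K: 298.0
  viscosity_Pa_s: 8.9e-4        # water near room temperature
  refractive_index: 1.3270      # deionised water at 976 nm

detector:
  xy_responsivity_V_per_m: 1.0e7
  sum_baseline_V: 5.0
  sum_responsivity_V_per_m: 2.0e6
  noise_sd_V: 0.01

sim:
  sampling_rate_hz: 10000.0
  duration_s: 120.0
  integrator_substeps: 1
  burn_in_s: 1.0
  integrator: euler

features:
  segment_duration_s: 0.5
  n_components: 2
  pca_scope: train_only         # 'global' reproduces a leaky-PCA reading

cv:
  n_folds: 6
  inner_folds: 5
  families: [random_forest, svm, knn, mlp]

output:
  store_traces: true
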