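# Synthetic two-group study: 12 + 12 subjects, 9 modules (47 nodes),
# three planted block effects and one behavior coupling.
design:
  n_subjects_per_group: 12
  n_modules: 9
  nodes_per_module: [4, 3, 4, 5, 6, 6, 8, 6, 5]
  n_timepoints: 300
  base_within_corr: 0.45
  planted_effects:
    - [EC, FPR, 0.3, 1]
    - [Med Vis, OP Vis, 0.25, 1]
    - [DMN, EC, -0.25, 1]
  behavior_couplings:
    - [EC, FPR, 1.0, 0.3]
  seed: 42
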