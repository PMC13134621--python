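{
  "schema": "sononeedle/calibrated-model/1",
  "composition": {
    "boronate_density": 800.0,
    "crosslink_density": 381.0091078560833,
    "chi": 0.3105883278254581,
    "solvent_molar_volume": 1.8e-05,
    "phi0": 0.2,
    "silica_fraction": 0.05,
    "silica_stiffening": 1.0
  },
  "binding": {
    "Ka": 1.2589254117941663e-09,
    "Kb": 2450.309517038307
  },
  "kinetics": {
    "collective_diffusivity": 1.2e-10,
    "length_scale": 0.0012,
    "n_modes": 10
  },
  "baseline_J": 1.0000000000000002,
  "fit_residual_rms": 0.23618850336867783,
  "provenance": "printed quasi-free SR table, 5-40 mM"
}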