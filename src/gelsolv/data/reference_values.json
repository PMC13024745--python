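{
  "comment": "Published study observations for the sulindac(SUL)-meglumine(MEG) hydrogel system, used as inputs by the reproduce report and the analysis drivers.",
  "delta_total_mpa_sqrt": {"sulindac": 23.74, "meglumine": 25.89},
  "delta_diff_mpa_sqrt": 2.15,
  "apparent_solubility_ug_per_ml": {
    "crystalline": 11.77,
    "physical_mixture": 3640.24,
    "hydrogel": 6432.13
  },
  "enhancement_fold": {"physical_mixture": 309.28, "hydrogel": 546.48},
  "supersaturation_720min_ug_per_ml": {
    "crystalline": 18.28,
    "physical_mixture": 255.57,
    "hydrogel": 276.17
  },
  "supersaturation_120min_ug_per_ml": {
    "crystalline": 16.3,
    "physical_mixture": 244.6,
    "hydrogel": 273.34
  },
  "supersaturation_fold_720min": {"vs_crystalline": 15.11, "vs_physical_mixture": 1.08},
  "cumulative_release_percent_20min": {
    "crystalline": 9.82,
    "physical_mixture": 52.31,
    "hydrogel": 77.41
  },
  "cumulative_release_percent_120min": {
    "crystalline": 35.75,
    "physical_mixture": 67.05,
    "hydrogel": 86.18
  },
  "phase_solubility_linear_range_mM": [0.048, 6.25],
  "molar_mass_g_per_mol": {"sulindac": 356.41, "meglumine": 195.21}
}
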