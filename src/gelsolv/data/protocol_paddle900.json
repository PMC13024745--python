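{
  "vessel_ml": 900.0,
  "aliquot_ml": 2.0,
  "dose_mg": 2.1,
  "temp_c": 37.0,
  "rpm": 100.0,
  "medium": "deionized water"
}
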