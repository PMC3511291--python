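# Healthy reference scenario: 24 kg subject, Vt 12 ml/kg, PEEP 5->20 cmH2O.
population:
  n_units: 18000
  mu_top: 42.4       # cmH2O
  sd_top: 23.0
  mu_tcp: 18.0
  sd_tcp: 8.0
  unit_volume: 0.05  # ml -> 900 ml recruitable capacity
  unit_compliance: 0.002  # ml/cmH2O per open unit (saturating elastic term)
  elastic_knee: 15.0
settings:
  weight_kg: 24.0
  vt_ml_per_kg: 12.0
  peep_schedule: [5.0, 10.0, 15.0, 20.0]
  breaths_per_level: 12
  resp_rate: 15.0
  sample_rate: 50.0
  resistance: 0.005
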