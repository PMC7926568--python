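name: synthetic-demo
base_year: 2020
horizon_end: 2030
practice_setting: primary
flags:
  apply_rate_of_change: true
  apply_support_adjustment: true
tables:
  population: population.csv
  indicators: indicators.csv
  services: services.csv
  cadres: cadres.yaml
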