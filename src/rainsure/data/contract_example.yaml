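crop: Dry beans - drought tolerant type
currency: US$
indemnity_rate: 5.0
min_mm:
- 0.0
- 10.0
- 10.0
- 25.0
- 40.0
- 40.0
- 40.0
- 30.0
- 0.0
premium: 3.0
soil: deep_sand
sowing_rule:
  run_length: 5
  threshold_mm: 5.0
sowing_window_doy:
- 135
- 166
station: San Dionisio INETER weather station
trigger_mm: -70.0
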