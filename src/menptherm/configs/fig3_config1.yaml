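# Collinear 3-particle cluster of MV-coated 120 nm particles, 30 nm gaps;
# amplitude inherited from the single coated particle 65 degC anchor.
scenario:
  kind: cluster
  configuration: config-1
source:
  mode: calibrated
  anchor_celsius: 65.0
  anchor_location: fluid_max
  calibration_reference: single_coated
run:
  t_end_s: 300.0
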