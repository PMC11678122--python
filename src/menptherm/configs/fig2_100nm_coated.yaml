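# MV-coated 100 nm particle at the amplitude calibrated on its bare
# counterpart (56 degC surface max): shows the coating's thermal damping.
scenario:
  kind: single_particle
  core_diameter_nm: 60
  coated: true
  domain_half_width_nm: 480
source:
  mode: calibrated
  anchor_celsius: 56.0
  anchor_location: surface
  calibration_reference: single_uncoated
run:
  t_end_s: 600.0
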