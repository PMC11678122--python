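# MV-coated 120 nm (80 nm core) particle anchored at the printed 65 degC
# extracellular maximum.
scenario:
  kind: single_particle
  core_diameter_nm: 80
  coated: true
source:
  mode: calibrated
  anchor_celsius: 65.0
  anchor_location: fluid_max
run:
  t_end_s: 600.0
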