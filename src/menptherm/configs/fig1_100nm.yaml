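# Single 100 nm (60 nm core + 20 nm shell) bare particle under saturation
# stimulation, anchored at the printed 56 degC surface maximum.
scenario:
  kind: single_particle
  core_diameter_nm: 60
  coated: false
source:
  mode: calibrated
  anchor_celsius: 56.0
  anchor_location: surface
run:
  t_end_s: 600.0
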