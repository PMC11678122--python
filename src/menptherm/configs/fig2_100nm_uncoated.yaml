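# Temperature-decay profile setting: bare 100 nm particle, 56 degC surface
# anchor; profiles written over 0-100 nm from the surface.
scenario:
  kind: single_particle
  core_diameter_nm: 60
  coated: false
  domain_half_width_nm: 480
source:
  mode: calibrated
  anchor_celsius: 56.0
  anchor_location: surface
run:
  t_end_s: 600.0
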