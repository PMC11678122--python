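# Cytokine-conjugated cluster, linking site B (facing away from the cluster).
scenario:
  kind: conjugated_cluster
  configuration: config-2
  site: B
source:
  mode: calibrated
  anchor_celsius: 65.0
  anchor_location: fluid_max
  calibration_reference: single_coated
run:
  t_end_s: 300.0
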