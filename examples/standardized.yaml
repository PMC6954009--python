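# Standardized baseline: homogeneous continuous landscape, low dispersal,
# small central pulse, full harvest-rate sweep.
landscape:
  kind: continuous
  dispersal: 2.5
disturbance:
  kind: square_local
  size: 0.01
  location: center
sweep:
  c_start: 1.8
  c_stop: 2.8
  c_step: 0.05
  mode: standardized
  scenario: continuous-lowD-small
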