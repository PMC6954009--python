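# Replicated random-disturbance campaign on a heterogeneous patchy
# landscape with low dispersal (reduce replicates for a quick look).
landscape:
  kind: patchy
  dispersal: 0.02
  heterogeneity:
    block_grid: 5
    r_low: 0.8
    r_high: 1.2
    sigma_m: 10.0
disturbance:
  kind: patch_local
  size: 1
  location: random
sweep:
  c_start: 1.8
  c_stop: 2.8
  c_step: 0.05
  replicates: 100
  mode: random
  scenario: patchy-lowd-random
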