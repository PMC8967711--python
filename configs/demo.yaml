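# Bundled demo configuration: two species, four shared inhibitory classes,
# one macaque-specific class, one excitatory outgroup branch; ~5,000 cells.
seed: 0
design:
  cells_per_branch: 450
fate:
  weight: 0.5
  cap: 1000
  top_n: 100
xspecies:
  k: 25
trajgenes:
  alpha: 0.05
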