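# Demo configuration: small synthetic four-species dataset.
sim:
  seed: 42
  n_families: 12
nlr:
  e_threshold: 1.0e-4
cluster:
  window_bp: 250000
dup:
  min_block_pairs: 5
  max_gap_ranks: 25
  proximal_max_rank_gap: 10
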