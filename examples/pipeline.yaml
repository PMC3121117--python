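# Full-pipeline configuration for a simulated study written by
#   glycolink simulate --seed 20750 --outdir scratch/sim
paths:
  expression: scratch/sim/expression.tsv
  metadata: scratch/sim/metadata.tsv
  networks: scratch/sim/networks.tsv
  lectin: scratch/sim/lectin.tsv
  lgg: scratch/sim/lgg_map.tsv
  network_enzymes: scratch/sim/network_enzymes.txt
config:
  fdr_threshold: 0.05
  fc_threshold: 2.0
  enrichment_alpha: 0.05
  gcp_alpha: 0.05
  n_random_networks: 2000
  rng_seed: 20750
  sample_scope_for_gcp: iPSC_only
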