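# Example pipeline configuration (scaled-down synthetic study).
seed: 1

simulate:
  proteome:
    n_proteins: 400
    frac_differential: 0.05
    effect_log2: 1.0
    sigma: 0.25
    batch_sd: 0.3
  phospho:
    n_sites: 300
    frac_differential: 0.05
    effect_log2: 1.5
    sigma: 0.3
    missing_steepness: 0.8
  rna:
    n_genes: 400
    target_corr: 0.47
  annotations:
    n_terms: 40
    term_size_range: [10, 40]
    n_planted: 4
  coreg:
    n_proteins: 120
    n_correlated_pairs: 25
    n_events: 15
    displacement: 5.0
  ppi:
    n_cliques: 2
    clique_size: 6
    background_edge_prob: 0.02

proteome:
  alpha: 0.01
  min_per_group: 3
  mc_reps: 20000

phospho:
  alpha: 0.05
  min_per_group: 2
  class1_threshold: 0.75
  mc_reps: 20000

enrichment:
  fdr: 0.05
  min_size: 5

kinase:
  p_threshold: 0.05

coreg:
  q_threshold: 0.01
  grubbs_alpha: 0.1
  consensus_p: 0.05

cluster:
  min_size: 3
  p_penalty: 2.0
  overlap_threshold: 0.8
  p_threshold: 0.1
  n_rewires: 100

rna:
  pseudocount: 1.0
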