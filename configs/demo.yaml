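# Demo pipeline configuration: a reduced synthetic cohort that exercises
# every stage in a few seconds.  Thresholds keep their published defaults.
seed: 7
simulate:
  enabled: true
  n_features: 600
  group_sizes: {HC: 8, APECED: 8, SjS: 8, SLE: 12}
  archetype_params:
    HC: {n_targets: 0, shift_mean: 0.0, shift_sd: 0.0, prevalence: 0.0}
    APECED: {n_targets: 20, shift_mean: 12.0, shift_sd: 2.0, prevalence: 0.85}
    SjS: {n_targets: 2, shift_mean: 10.0, shift_sd: 1.5, prevalence: 1.0}
    SLE: {n_targets: 60, shift_mean: 8.0, shift_sd: 2.0, prevalence: 0.9}
  repertoire_params:
    HC: {n_clones: 200, concentration: 1.0, depth: 5000, mutation_mean: 20.0}
    APECED: {n_clones: 200, concentration: 0.2, depth: 5000, mutation_mean: 13.0}
    SjS: {n_clones: 200, concentration: 2.0, depth: 5000, mutation_mean: 14.0}
    SLE: {n_clones: 200, concentration: 5.0, depth: 5000, mutation_mean: 14.0}
  n_genes: 200
normalize:
  span: 0.4
  iterations: 2
zscore:
  k_max: 3
  alpha: 0.01
reactivity:
  z_reactive: 5.0
  prevalence_min: 0.30
  n_top_variance: 100
  n_top_rank: 4000
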