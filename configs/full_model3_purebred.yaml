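model_id: 3
training_mode: purebred
w_values:
- 0.0
- 0.25
- 0.5
- 0.75
- 1.0
n_generations: 40
n_replicates: 50
master_seed: 1
genome:
  n_chromosomes: 4
  chromosome_length: 1.0
  n_snps_target: 4000
  n_qtl_target: 400
  n_candidate_loci: 8800
  mutation_rate: 2.5e-05
  historical_size: 2000
  historical_generations: 2000
  maf_threshold_arch: 0.05
trait:
  sigma2_p: 1.0
  h2: 0.3
  sigma2_d_target: 0.1
  overdominance_allowed: false
  literal_unit_residual: false
selection:
  n_founders: 100
  n_expansion_generations: 100
  n_candidates: 1000
  n_males_selected: 100
  n_females_selected: 200
  n_purebred_offspring: 1000
  n_crossbred_offspring: 1000
chain:
  n_iter: 20000
  burn_in: 3000
  df: 5.0
  r2: 0.5
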