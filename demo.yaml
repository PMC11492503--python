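# Demo pipeline configuration: synthetic cohort -> scan -> instruments ->
# PheWAS -> MR. Same content as mirqtl.pipeline.DEMO_CONFIG.
seed: 7
outdir: results/demo
simulate:
  n_samples: 1200
  n_phenome_samples: 20000
  blocks:
    - {n_variants: 30, rho: 0.8, chrom: "1", start_pos: 1000000}
    - {n_variants: 30, rho: 0.6, chrom: "1", start_pos: 2000000}
    - {n_variants: 30, rho: 0.0, chrom: "2", start_pos: 5000000}
  mirnas:
    - mirna_id: miR-sim-1
      chrom: "1"
      mature_start: 1060000
      effects:
        - {variant_index: 10, beta: 0.45}
        - {variant_index: 20, beta: 0.35}
    - mirna_id: miR-sim-2
      chrom: "1"
      mature_start: 2060000
      effects:
        - {variant_index: 40, beta: 0.5}
    - mirna_id: miR-sim-3
      chrom: "2"
      mature_start: 5050000
      effects: []
  residual_sd: 1.0
  phenome:
    n_phecodes: 12
    prevalence: 0.05
    effect_per_sd: {"0": 0.25}
scan:
  covariates: [age, sex, pc1, pc2, pc3, pc4, pc5]
  cis_window: 500000
  alpha_gw: 5.0e-8
  n_phenotypes: 2083
instruments:
  q_threshold: 0.1
  clump_r2: 0.1
  window: 500000
phewas:
  min_cases: 200
  q_alpha: 0.05
mr:
  min_instruments: 3
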