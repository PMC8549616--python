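# Full-pipeline demo on synthetic data: `multistress run --config examples/run.yaml`
synthetic:
  n_genotypes_per_pop: 6
  n_replicates: 3
  population_effects:
    PP: {fecundity: 2.0, size_mm: 0.3}
    CWP: {size_mm: -0.2}
  treatment_effects:
    HA: {fecundity: 1.0, size_mm: 0.2, age_days: -0.5}
    LA: {fecundity: -3.0, size_mm: -0.5, age_days: 1.5}
    HI: {fecundity: -2.0, size_mm: -0.3, age_days: 1.0}
    LI: {fecundity: -1.0, size_mm: -0.1, age_days: 0.5}
    HAHI: {fecundity: -1.0, size_mm: -0.1, age_days: 0.5}
    HALI: {fecundity: 0.0, size_mm: 0.1, age_days: 0.0}
    LAHI: {fecundity: -7.0, size_mm: -0.8, age_days: 2.5}   # synergistic on fecundity
    LALI: {fecundity: -4.0, size_mm: -0.6, age_days: 2.0}
  sd_genotype: 1.0
  sd_batch: 0.2
  sd_residual: 1.0
  hazard:
    scale: 120.0
    shape: 1.0
    log_hazard_arm: {LAHI: 0.8, LALI: 0.5}
  seed: 7
standardize_mode: paper_literal
bootstrap_reps: 500
interaction_seed: 7
outdir: scratch/demo_run
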