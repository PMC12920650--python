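# longrrm

Random regression modelling of longitudinal phenotypes with genomic
relationship matrices: estimate how additive-genetic and individual-specific
variance components of a repeatedly measured trait (log-BMI across childhood
in the motivating application) change continuously with age.

The pipeline covers:

- **Legendre bases** (`longrrm.basis`): age standardization to [-1, 1] and
  orthonormal Legendre polynomial coefficient/basis matrices.
- **Synthetic cohorts** (`longrrm.simulate`): genotypes, longitudinal
  trajectories with genetic covariance `A ⊗ Kg` over the realized genomic
  relationship matrix, individual effects, source offsets, irregular
  measurement schedules and optional genetic-value-dependent dropout, plus
  ground-truth records for recovery tests and synthetic adult-trait PGS
  weights.
- **Phenotype cleaning** (`longrrm.pheno`): EWMA/robust-z implausible-value
  flagging, age-window and minimum-measurement inclusion filters with an
  exclusion report.
- **Genomic relationships** (`longrrm.grm`): SNP QC (missingness, exact HWE,
  INFO, MAF), GRM construction, greedy relatedness pruning, GRM principal
  components, GCTA-compatible binary GRM I/O and minimal PLINK bed/bim/fam
  I/O.
- **AI-REML** (`longrrm.reml`): Henderson mixed-model equations with
  Kronecker-structured genetic (`A ⊗ Kg`) and individual (`I ⊗ Ki`)
  covariances; EM warm-up followed by average-information Newton steps in
  Cholesky/log coordinates; reduced (individual-only), PGS-adjusted and
  per-year heterogeneous-residual variants; AIC/LRT model comparison.
- **Age-scale surfaces** (`longrrm.surfaces`): `Φ K Φ'` transforms,
  heritability and correlation surfaces with delta-method standard errors.
- **Genetic PCA** (`longrrm.genpca`): eigendecomposition of `Kg`,
  eigenfunctions of age, chi-square variance-share tests, simulation CIs for
  eigenvalue shares, PC polygenic scores with ±1 SD strata.
- **GWAS** (`longrrm.gwas`): reduced-model BLUP trajectory phenotypes,
  vectorized per-SNP OLS with PC covariates, genomic-control lambda,
  window-based clumping and summary-statistic I/O.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
values recomputed from published coefficient estimates, dense-oracle REML
equivalence, a GREML special-case cross-check, a 20-replicate parameter
recovery study at N=500, test calibration and GWAS diagnostics). The
recovery study dominates the runtime (~10–15 min on one CPU).

## CLI

```bash
longrrm simulate --config sim.yaml --out cohort/ --seed 1
longrrm clean    --pheno cohort/pheno.tsv --out clean.tsv --report report.json
longrrm grm      --bfile cohort/geno --out cohort/grm --prune 0.05 --pca 10
longrrm fit      --pheno clean.tsv --grm cohort/grm --spec spec.yaml --out fit/
longrrm transform --fit fit/ --ages 1:18 --out surfaces/
longrrm pca      --fit fit/ --out pca/ --nsim 10000 --seed 1
longrrm gwas     --bfile cohort/geno --pheno derived.tsv --covar pcs.tsv --out gwas
```

`spec.yaml` mirrors the model menu, e.g.

```yaml
k_f: 4          # fixed cubic per sex
k_g: 3          # quadratic genetic component
k_i: 3          # quadratic individual component
residual_structure: homogeneous   # or per-year
```

## Notes

- GRMs built with in-sample allele frequencies are exactly singular (the
  centering direction); the REML engine floors GRM eigenvalues at `1e-3` of
  their mean (`longrrm.reml.regularize_grm_matrix`) so the mixed-model
  equations are well-posed. External likelihood checks should target the
  same regularized matrix.
- The INFO-score QC filter is inert for hard-call panels without imputation
  scores (simulated data); it only applies when a panel carries scores.
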