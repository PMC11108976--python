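# scovnet

Structural covariance network analysis of regional gray-matter volumes,
centered on the amygdala subnuclei.

Given a subject-by-region volume table and a covariate table (age, sex,
total brain volume, group), the pipeline:

1. validates the cohort against a canonical 105-region registry
   (63 cortical DKT regions, 24 subcortical regions, 18 amygdala
   subnuclei) and runs an interquartile-range outlier report;
2. aggregates the nine per-hemisphere subnuclei into three composite
   nuclei (BLA, CMA, SFA) and residualizes volumes on age, sex and
   total brain volume within each group;
3. builds per-group Pearson association matrices and compares each
   nucleus' 87-region covariance profile — Dunn & Clark z tests for
   within-group (dependent, overlapping) comparisons, Fisher z tests
   for between-group comparisons, Zou confidence intervals, per-family
   Benjamini-Hochberg FDR, and a Bonferroni threshold over the number
   of nucleus comparisons;
4. binarizes the association matrices over a density sweep (from the
   minimum density connecting both groups up to 50% in 2% steps),
   computes nodal degree, betweenness and clustering, integrates them
   across the sweep, flags hubs (> mean + 2 SD), and generates
   Hirschberger–Qi–Steuer random covariance matrices as a null
   topology reference;
5. runs label-permutation tests on the density-integrated metrics
   (FDR across nodes, alpha split over the three regional measures)
   and covariate-adjusted linear models of nucleus volumes.

A synthetic-cohort module generates two-group cohorts from a
latent-factor correlation model with known ground truth, including
scenarios with an injected covariance difference, a planted topological
hub, and a group volume shift.

## CLI

```sh
# generate a synthetic cohort
scovnet simulate --scenario A-null --seed 1 --out data/

# full pipeline
scovnet run --volumes data/volumes.csv --covariates data/covariates.csv \
            --config cfg.yaml --out results/

# individual stages
scovnet qc --volumes ... --covariates ... --out results/
scovnet volumes --volumes ... --covariates ... --analysis nine_nuclei --out results/
```

Configuration (YAML) keys and defaults: `analysis: three_nuclei`,
`covariates: [age, sex, tbv]`, `fdr_family_size: 87`,
`density_step: 0.02`, `density_max: 0.5`, `permutations: 1000`,
`null_matrices: 20`, `seed: 0`, `alpha: 0.05`. Every run writes stage
TSVs plus `manifest.json` (seed, config hash, output checksums); reruns
with the same inputs and seed are bit-identical. Exit codes: 0 ok,
2 validation error, 3 compute error.

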