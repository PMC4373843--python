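# comethnet

Signed weighted co-methylation network analysis for 450K-style DNA
methylation data, with an estimator for how much a condition — here
HIV-1 infection — accelerates age-related methylation change.

Aging leaves a reproducible imprint on the methylome: clusters of CpG
sites ("co-methylation modules") gain or lose methylation together as
people get older. If a disease pushes the same sites in the same
direction, its effect can be expressed in *years*: fit the module's
summary profile on age and disease status and take the ratio of the two
coefficients. `comethnet` implements this analysis end to end for
epigenomics researchers working with Illumina 450K-style beta-value
matrices, and ships a synthetic-cohort generator with planted ground
truth so every stage can be validated quantitatively.

## The model in brief

* **Network.** For probes *i*, *j* with methylation profiles across
  samples, the signed adjacency is `a_ij = ((1 + cor(x_i, x_j))/2)^p`
  (default soft power p = 12), combined into the topological overlap
  measure `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`.
  Average-linkage clustering of `1 − TOM` plus a simplified
  dynamic-hybrid branch cut yields co-methylation modules.
* **Module eigenvector and kME.** Each module is summarised by the first
  principal component of its standardized methylation matrix (one score
  per sample, sign-fixed to track mean methylation); a probe's module
  membership kME is its correlation with that eigenvector, and probes
  with kME > 0.85 are intramodular hubs.
* **Acceleration.** For an age-related module, ordinary least squares

      ME(s) = β₀ + β_age·age(s) + β_HIV·hiv(s) + ε(s)

  gives the acceleration estimate `β_HIV / β_age` in years, with a
  delta-method standard error.
* **Preservation.** Whether a module found in one cohort exists in
  another is scored by permutation Z statistics of density and
  connectivity; `Z_summary` < 2 means not preserved, 2–10 weak to
  moderate, > 10 strong.
* **Supporting stages.** Per-sample beta-mixture quantile normalization
  of Infinium type-II probes; paired/unpaired per-CpG screens with
  Storey q-values; reference-free cell-composition adjustment with the
  latent dimension set by random matrix theory; Fisher exact gene-set
  and module-overlap tests.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

Simulate a matched-pair cohort (24 seropositive/seronegative pairs, 2000
probes) containing one planted module of 300 CpGs whose latent factor
rises by 0.01 per year of age with a seropositive offset of 0.14 — a
planted acceleration of 14 years — then run the pipeline:

```sh
comethnet simulate -o cohort --seed 1
comethnet normalize -b cohort/beta.tsv -m cohort/manifest.tsv -o norm
comethnet modules -b norm/beta_normalized.tsv -o mods
comethnet accelerate -b norm/beta_normalized.tsv -s cohort/samples.csv \
    --modules mods/modules.tsv --module-label 1
```

which prints:

```
wrote cohort (2000 probes x 48 samples) to cohort
normalized 48/48 samples
detected 1 modules: {1: 517}
                  estimate        se             p
Intercept        -0.490327  0.036057  1.511705e-17
Age               0.011092  0.000921  1.144255e-15
HIV Seropositive  0.163742  0.017252  2.599047e-12
Estimate of accelerated aging: 14.8 years (SE 2.0)
```

Reading the output: the detected module (517 probes: the planted 300
plus a weakly correlated halo) has an eigenvector that rises
significantly with age (β_age = 0.0111 per year) and is additionally
elevated in seropositive samples (β_HIV = 0.164); the offset corresponds
to 0.164/0.0111 ≈ 14.8 years of age-related change, within two standard
errors of the planted 14. The same functions are available as a library
(`comethnet.simulate_cohort`, `signed_adjacency`, `topological_overlap`,
`detect_modules`, `module_eigenvector`, `fit_acceleration`, …) for use
on real beta matrices.

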