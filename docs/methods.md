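# Methods

`comethnet` analyses 450K-style DNA methylation data with signed weighted
correlation networks, estimates HIV-associated acceleration of age-related
methylation from a module eigenvector regression, and validates every
stage against a synthetic-cohort generator with planted ground truth.
This note records the models, the defaults and why, the numerical choices,
and what the validation does and does not show.

## Data model

Methylation at a CpG is summarised by the beta value
`β = max(M,0) / (max(M,0) + max(U,0) + 100)`, the regularised fraction of
methylated signal, in [0, 1). Cohorts are probes × samples `BetaMatrix`
objects with per-sample covariates (age in years; HIV serostatus coded
0 = seronegative, 1 = seropositive; optional matched-pair ids; numeric
traits such as cell-subset counts) and a probe manifest carrying the
Infinium chemistry type (I or II) and gene annotation. Missing betas are
allowed; correlations use pairwise-complete samples, and probes missing in
more than 20% of samples are dropped with a warning (configurable — the
threshold keeps pairwise correlations stable at desk-scale sample sizes).

## Synthetic cohorts

The generator emulates a matched-pair PBMC methylation study:

* `n_pairs` seropositive/seronegative pairs (default 24, i.e. 48 samples),
  each pair sharing an age drawn uniformly from 20–56 years — matching is
  exact by default, with optional jitter for robustness experiments;
* a background of probes whose logit-scale baselines follow a bimodal
  mixture (peaks near β ≈ 0.08 and β ≈ 0.85 with a smaller intermediate
  component), mimicking the characteristic two-humped 450K beta
  distribution;
* planted co-methylation modules: module *m* has a latent factor
  `f_m(s) = α_age·age_s + γ_hiv·hiv_s + N(0, σ_f²)` and probe *j* carries
  it as `β_js = expit(baseline_j + loading_j·(f_m(s) − mean f_m) + ε_js)`.
  Planting on the logit scale keeps betas inside [0, 1] without clipping,
  which would otherwise distort the correlation structure. The default
  module has 300 probes, `α_age = 0.01`/year, `γ_hiv = 0.14` (planted
  acceleration ratio `γ_hiv/α_age = 14` years), loadings uniform in
  (0.8, 1.2), baselines uniform in (−1.5, 1.5), latent noise σ_f = 0.05
  and probe noise σ_ε = 0.1 — chosen so that within-module correlations
  (≈ 0.6) and eigenvector–trait correlations sit in the range typical of
  reported co-methylation modules;
* Infinium type-II compression: `apply_type2_bias` maps type-II probes to
  `0.5 + squeeze·(β − 0.5)` (default squeeze 0.8), the dynamic-range
  compression that intra-array normalization must undo;
* optional cell-type-mixture confounding: per-sample Dirichlet cell
  proportions (optionally serostatus-dependent) mix per-cell-type pure
  profiles that differ at a configurable fraction of probes.

All draws come from named RNG streams derived from one seed, so adding a
component never shifts another component's stream and identical seeds give
bit-identical cohorts. Probe-level architecture (baselines, loadings,
chemistry assignment, genes) can be pinned by a separate `probe_seed`, so
two configs sharing it emulate two cohorts assayed on the same array with
independent participants — the setting in which module preservation is a
meaningful question.

What the generator does *not* emulate: chip/batch effects, probe-level SNP
artifacts, sex chromosomes, realistic linkage between neighbouring CpGs,
or the heavy-tailed noise of real arrays. Passing tests therefore show
that the algorithms recover the structure they target under idealised but
realistically scaled conditions; they are not evidence about artifact
robustness on real data.

## Beta-mixture quantile normalization

The two Infinium chemistries yield different beta distributions, type II
being range-compressed. Per sample, three-state beta mixtures
(unmethylated / hemimethylated / methylated) are fitted to the type-I and
type-II values by EM with exact weighted maximum-likelihood M-steps
(Newton on the digamma score equations, damped to preserve the EM ascent
property; the log-likelihood trace is monotone to 1e-8). Initialization is
deterministic — values cut at empirical terciles, each group seeding a
state by method of moments — and the type-II fit is warm-started from the
type-I fit so the two decompositions track one likelihood basin. Values
are clamped to [1e-6, 1 − 1e-6] before fitting (the beta density is
undefined at the boundary); inputs with fewer than 30 usable values or no
spread are rejected.

The correction maps each type-II value through the fitted mixture CDFs,
`β' = F_I⁻¹(F_II(β))`, inverted on a 4001-point grid. We map through the
*full* mixture rather than state-by-state because the three-state
decomposition of a smooth beta density is only weakly identified — two
fits of the same distribution can disagree substantially on weights while
agreeing on the density — so maps between individually fitted components
carry an irreducible instability (~0.04 mean absolute drift on our data),
while the overall fitted CDF is pinned down by the data. The full-mixture
map is strictly monotone, is the identity when the two fitted
distributions coincide, normalizing twice moves values by < 0.01 on
average, and it strictly reduces the type I/II Kolmogorov–Smirnov distance
in every sample of the default simulation. A state-merged ("degenerate")
fit is still a proper density, so such samples are normalized rather than
skipped: leaving a minority of samples uncorrected plants a sample-level
type-II batch factor that the network stage would pick up as large
artifact modules.

## Signed network, TOM, and module detection

The network is signed and soft-thresholded:
`a_ij = ((1 + cor(x_i, x_j))/2)^power` with Pearson correlation across
samples, so anti-correlated probes are unconnected. The default power is
12, the customary choice for signed networks; a scale-free-fit diagnostic
(`scale_free_fit`) is provided but never used for automatic selection.
Adjacency is combined into the topological overlap measure
`TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, with `L_ij` the
shared-neighbour sum and `k_i` the connectivity (both excluding
self-edges), and `1 − TOM` is clustered by average-linkage hierarchical
clustering.

Branch cutting is a simplified dynamic-hybrid procedure:

1. a static cut of the dendrogram at absolute height 0.995 (heights are
   TOM dissimilarities in [0, 1]) yields candidate branches; branches
   smaller than `min_module_size` (default 20) dissolve into the
   unassigned background, label 0;
2. each surviving branch is pruned of members whose correlation with the
   branch eigenvector (kME) is below 0.3 — topological overlap attaches a
   halo of weakly connected probes to any highly connected branch, and
   kME is what separates core from halo;
3. a branch survives only if its core still reaches `min_module_size`
   members and mean core kME ≥ 0.6, the mean being computed against the
   *unpruned* branch eigenvector so the check is not inflated by the
   pruning itself. On unstructured data the first principal component of
   an incidental branch rarely exceeds mean kME ≈ 0.45 at n ≈ 48 samples,
   so this cohesion gate is what keeps the null case clean;
4. background probes are reassigned to a module if their kME against its
   recomputed eigenvector exceeds 0.5.

Modules are numbered 1, 2, … by decreasing size; 0 is reserved for the
background. Detection is invariant to probe order up to relabelling. The
procedure intentionally omits the many undocumented heuristics of the full
published dynamic-hybrid algorithm; ground-truth recovery tests (two
orthogonal planted modules recovered with Rand index ≥ 0.95; no sizeable
modules on pure noise in 10/10 seeds) validate that the simplification
retains the properties the analysis relies on. At the default scale the
whole matrix is processed in a single block; for much larger probe sets a
pre-clustering blocking strategy would be needed, which is out of scope.

The module eigenvector is the first right singular vector of the
row-standardized module matrix (unit-norm sample scores), sign-fixed so
its correlation with the mean standardized module profile is non-negative
— hence a module that gains methylation with age has a positive
eigenvector–age correlation. kME is the Pearson correlation of a probe
with an eigenvector; its p-value uses the exact t transform
`t = r·sqrt(n−2)/sqrt(1−r²)` with n − 2 degrees of freedom. Hub probes are
those with kME above a threshold (default 0.85, yielding a short
gene-annotated list on the default simulation).

## Module preservation

Whether a reference partition survives in an independent cohort is
quantified by permutation Z statistics computed in the test network: two
density statistics (mean within-module adjacency and correlation) and
three connectivity statistics (reference–test correlations of intramodular
connectivity, of the within-module correlation matrix off-diagonals, and
of kME). Each observed statistic is standardized against `n_permutations`
(default 200, minimum 50) random probe sets of the same size drawn from
the shared probe universe; `Z_density` and `Z_connectivity` are the
medians of their groups and `Z_summary` their mean. Bands: < 2 not
preserved, 2–10 weak-to-moderately preserved, > 10 strongly preserved.
This is a deliberately reduced statistic set — the published framework
defines ~20 statistics, but only the composite is consumed downstream.

Caveat: when the probe universe is dominated by unstructured background
and contains few modules, the connectivity nulls are inflated (a random
set mixes module and background probes, whose connectivity contrast is
itself reproducible across cohorts), making `Z_connectivity` conservative;
`Z_summary` is then carried by the density terms. Null draws may by chance
include observed-module probes — the standard permutation contract.

## Screening and inference

* Paired serostatus screen: per probe, a one-sample t-test on the
  seropositive-minus-seronegative pair differences; the volcano-style
  effect summary is `sign(mean difference)·(−log10 p)` (log base 10).
* Unpaired screen: equal-variance two-sample t by default (Welch by
  flag), with Storey q-values — `π0` estimated on a λ-grid
  (0.05…0.95), smoothed by a cubic polynomial and read off at λ = 0.95;
  forcing `π0 = 1` reduces the procedure exactly to Benjamini–Hochberg.
* Age effects: per-probe Pearson correlation with age (all samples by
  default; a subset selector allows e.g. seronegatives only).
* Acceleration model: OLS of a module eigenvector on [1, age, hiv]. The
  headline quantity is `acceleration_years = β_hiv / β_age`, the
  seropositive offset expressed in years of age-related methylation
  change. Its standard error uses the delta method,
  `SE ≈ |ratio|·sqrt((SE_h/β_h)² + (SE_a/β_a)² − 2·cov/(β_h·β_a))`, and a
  normal-approximation confidence interval. The ratio is scale-free: the
  eigenvector's arbitrary normalization cancels. Rank-deficient designs
  (e.g. age constant within serostatus) are rejected.
* Hypermethylation count: for a module and two sample groups, the count
  of CpGs whose group-mean difference is positive, tested against a fair
  coin by an exact two-sided binomial test with ties excluded. The
  sign-count formulation is this package's documented interpretation of
  "a greater number of hypermethylated CpGs"; it is not claimed to match
  any particular original test.

## Reference-free cell-composition adjustment

Stage 1 regresses every probe on [1, covariates] (default age and
serostatus) and collects the residual matrix. Stage 2 sets the latent
dimension k by random matrix theory: residual columns are standardized and
the eigenvalues of `Z Z'/p` are counted above the Marchenko–Pastur bulk
edge. Two finite-sample corrections matter: projection onto the residual
space reduces the noise rank to `df = n − (design columns)`, and column
standardization re-inflates the spectrum by `n/df`, so the edge used is
`(n/df)·(1 + sqrt(df/p))²`. With the naive edge, regression residuals
produce spurious latent dimensions. The eigenvalue count is a hard
threshold at an asymptotic edge, so finite-size (Tracy–Widom) fluctuations
can occasionally add one dimension on pure noise; where a stable summary
is needed (the acceptance script) the median over five replicate draws is
reported.

The latent sample scores are the centred raw data projected onto the
top-k *right* singular vectors (probe loadings) of the residual matrix,
and the per-probe regressions are refitted with these scores appended.
The projection through probe loadings is essential: the residuals pin
down the confounder's loading pattern, and projecting the raw data onto
it recovers the full confounder score including the component correlated
with the covariates — the part an adjustment must absorb. (Appending the
residuals' own left singular vectors would leave every covariate
coefficient exactly unchanged, since residuals are orthogonal to the
design.) With `k = 0` the adjusted and unadjusted tables are identical;
on simulations with serostatus-correlated cell mixtures the adjustment
shrinks per-CpG HIV coefficients toward their confounder-free values.

## Set-overlap statistics

Module annotation reduces to 2×2 tables over a stated identifier universe
(probes for cross-study module overlap, deduplicated gene symbols for
gene-set tests): the sample odds ratio `n11·n00/(n10·n01)` (infinite when
a denominator cell is zero with positive numerator) and the two-sided
Fisher exact p-value summing all tables with point probability at most
the observed one. Gene sets are read from standard GMT files. The choice
of universe is the caller's; it materially affects the result and no
default is imposed.

## Validation strategy and problem sizes

Every numerical kernel is checked against an independent oracle: TOM
against an explicit triple-loop computation (1e-12), correlation and
t-test p-values against numerical integration of the t density (1e-8),
Fisher p-values against full hypergeometric enumeration, Storey q-values
against a direct Benjamini–Hochberg implementation. Pipeline behaviour is
validated on planted ground truth: the full chain (type-II bias →
normalization → network → detection → eigenvector → regression) run on
ten cohorts of 48 samples × 2000 probes recovers the planted 14-year
ratio within ±25% on average, and the delta-method interval covers the
planted ratio in ≥ 80% of 50 replicates. Preservation uses 2000-probe
cohorts with 200 permutations. These sizes keep a complete validation run
in the low minutes on one core while leaving all qualitative behaviour
(halo formation, null calibration, confounding shrinkage) intact;
reported co-methylation analyses at full array scale (~485k probes) would
require the blocking strategy noted above.

## Known limitations

* The dynamic-hybrid simplification can admit a small halo tail (kME
  0.3–0.5) into a strong module and occasionally emits a borderline small
  module on structured-noise seeds; hub lists (kME > 0.85) are unaffected.
* The preservation connectivity statistics are conservative in
  background-dominated universes (see above).
* The q-value π0 smoother falls back to the minimum-over-grid estimate
  below 100 tests.
* The acceleration ratio's delta-method interval assumes β_age is well
  separated from zero; for modules with no age signal the ratio itself is
  not meaningful.
* BMIQ-style correction assumes both probe types are present per sample
  and at least 30 values per type.
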