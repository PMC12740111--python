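# Methods

`methclock` implements an epigenetic-aging analysis for organisms profiled
for two DNA modifications — N6-methyladenine (6mA, bedMethyl code `a`) and
5-methylcytosine (5mC, code `m`) — from per-site modified-base call tables
(the 18-column Modkit "pileup" bedMethyl dialect). The pipeline covers:
coverage filtering and complete-case matrix assembly, differential
methylation between extreme age groups, site-level methylation entropy,
per-site rate of change (ROC), three penalized-regression age predictors
("clocks") trained by nested leave-one-out cross-validation, permutation
significance, feature-selection stability, and detection of
treatment-induced epigenetic age deceleration. A synthetic aging-methylome
generator makes every stage testable without sequencing data.

## Data model

A *site* is a (contig, 0-based position, strand, modification code) tuple.
Strands are never collapsed: 6mA carries no palindromic-context guarantee,
so the two strands are independent observations. Each sample contributes
per-site counts (modified reads `n_mod`, valid reads `n_valid`); the
methylation fraction is always recomputed as `n_mod / n_valid` rather than
trusted from the printed percent column. Sites below the coverage floor
(default 10X) are dropped per sample, and the multi-sample matrix keeps
only sites observed in *every* sample (complete case; no imputation — at
n = 15 imputation artifacts would be a larger risk than the site loss).

Global methylation is reported read-weighted (`100 * Σ n_mod / Σ n_valid`)
by default, with the site-weighted mean (mean of per-site fractions)
available, since published "percent methylated" summaries are ambiguous
between the two.

## Differential methylation

Sites are tested between the youngest and oldest untreated groups.
Replicate counts are pooled within each group (the standard count-based
DMR-caller convention) and tested with a two-sided Fisher's exact test on
the 2x2 modified/unmodified table; Benjamini-Hochberg q-values are
computed within each modification channel, and sites with `q < 0.05` are
called DMS. The effect size is `mean fraction(old) − mean fraction(young)`
(positive = hypermethylation with age). The absolute difference of
beta-posterior MAP estimates under a uniform Beta(1, 1) prior is carried
as a descriptive score only — with that prior the MAP equals the observed
fraction, so the score is the absolute pooled-fraction difference. A
per-replicate Welch t-test on fractions is available as a sensitivity
option. Bayesian likelihood scoring of the sort used inside Modkit's
`dmr pair` is deliberately not reproduced: a fully specified,
oracle-checkable test was preferred.

Direction proportions (hypo vs hyper) of the two channels are compared by
Pearson chi-squared on the 2x2 table with Yates continuity correction
(default on, the convention for 1-df tables). Genomic context is assigned
from a BED4 feature file with priority rDNA > ncRNA > coding, falling back
to intergenic.

## Methylation entropy

Site-level entropy is the binary Shannon entropy of the methylation
fraction in bits, `H(p) = −p log2 p − (1−p) log2 (1−p)`, already
normalized to [0, 1]; sample-level entropy is its mean over a site set
(genome-wide or DMS-restricted). Because each site is a two-state system,
this mean equals the genome-normalized entropy of the Hannum-style
construction. Natural-log units are available behind a flag.

Group comparisons run one-way ANOVA with Tukey HSD only when every group
passes Shapiro-Wilk normality and Levene's homoscedasticity test at
alpha = 0.05; otherwise Kruskal-Wallis with pairwise Mann-Whitney post hoc
tests, BH-adjusted (the nonparametric adjustment choice mirrors the DMS
procedure). The gate outcome is always reported.

## Rate of change

Each site gets an OLS regression of methylation level (percent) on age
(weeks); the slope is the site's ROC in % per week. Sites with
`p < 0.05` and `R² >` a configurable threshold (default 0.65; 0.5 is the
other convention in circulation, and both are reported by the pipeline)
are averaged to the mean ROC. Two caveats are intrinsic and documented
rather than hidden:

* **Retention bias.** The filtered mean estimates the mean slope of the
  *retained* subset, not of all drifting sites: significance/R² filters
  select large and noise-inflated slopes (winner's curse). Parameter
  recovery is therefore assessed on the drifting-site set without
  retention filtering, while the filtered mean remains the pipeline's
  headline descriptive statistic.
* **Nominal vs realized slope.** The generator drifts sites on the logit
  scale; its nominal "% per week" is the fraction-scale derivative at the
  midpoint age. What a linear regression over a symmetric equal-n age
  design estimates is exactly the *window-average* rate
  `100 (p(oldest) − p(youngest)) / Δweeks`. Both are recorded in the
  simulation truth; recovery is judged against the realized window rate.
  At low baselines the two differ (saturating negative-slope sites push
  the nominal comparison up by as much as 2x).

## Epigenetic clocks

Three clock types predict chronological age (days):

| clock | penalty (glmnet mixing) | features |
|---|---|---|
| `elasticnet_levels` | elastic net, rho = 0.5 | all sites' fractions |
| `ridge_dms` | ridge, rho = 0 | fractions at DMS |
| `elasticnet_entropy` | elastic net, rho = 0.5 | site entropies at DMS |

The objective is the glmnet parameterization
`(1/2n)‖y − Xw‖² + λ [ρ‖w‖₁ + (1−ρ)/2 ‖w‖²]`. Training is a nested
leave-one-out cross-validation over the training samples (default 10 of
15, stratified by age group with a largest-remainder allocation; the same
split serves all clock types): the outer loop holds out one sample for
performance estimation, and an inner leave-one-out loop over the remaining
samples picks λ minimizing held-out squared error. Cross-validated MAE
(days), MRE (% of chronological age: `100 · mean(|ŷ−y|/y)`) and Pearson r
come from the outer-fold predictions; the deployed model is refit on all
training samples at the λ chosen by a full-training LOOCV, and evaluated
once on the untouched test samples.

Numerical choices:

* λ grid: 100 log-spaced values from `λ_max = max|X'y|/(n ρ)` (the
  smallest penalty with an all-zero elastic-net solution) down to
  `0.01 λ_max` when p > n, `10⁻⁴ λ_max` otherwise (glmnet's convention).
  For ridge, `λ_max` is anchored with ρ floored at 10⁻³ (again glmnet's
  convention), which inflates it ~1000-fold, so the ridge grid descends to
  `10⁻⁷ λ_max`; its path is closed-form via one SVD per fold, so the long
  grid is free.
* Ties in inner MSE resolve toward the larger (sparser) λ.
* The inner grid walk uses warm-started coordinate descent
  (scikit-learn's Cython core when importable, the public `enet_path`
  otherwise) and stops 15 grid points past the running MSE minimum — the
  held-out error is U-shaped in λ in practice, and the dense small-λ tail
  dominates runtime. Solver tolerance is 10⁻³ (coefficient differences vs
  10⁻⁴ are ~10⁻³ on the standardized scale, far below fold noise).
* Features are standardized inside each fold; coefficients are
  back-transformed to the original scale. Zero-variance features are
  dropped with a warning (they carry no signal and break standardization).
* Predictions are never clamped; negative ages are reported as-is.

Permutation significance reruns the full nested procedure on shuffled ages
(default statistic: cross-validated MAE) with the add-one estimator
`p = (1 + #{permuted ≥ as good}) / (n_perm + 1)`, so p is never zero.
Feature-selection stability is the coefficient of variation of per-fold
nonzero-feature counts (sample-SD convention by default, population-SD
also reported); ridge models return CV = 0 with an explanatory flag since
they select nothing. The per-fold selected-site sets are retained: a
sparse MSE-optimal refit deliberately omits redundant correlated sites, so
"which sites does the clock use" is best answered by the union of
selections across folds.

One artifact worth knowing: under the null (no age signal), LOOCV r is not
near zero but strongly *negative* — when the penalty zeroes every
coefficient, the fold prediction is the leave-one-out training mean, an
exactly decreasing function of the held-out age. Null behaviour should be
judged by the permutation test, or one-sidedly (no positive r), never by
|r| being small.

Age deceleration: a trained clock predicts each treatment arm and the
same-age controls; arms are compared with the gated group test on the
predicted ages, reporting per-arm mean predicted age, the post hoc p
versus control and the sign of the difference.

## Synthetic cohort generator

The generator emulates a three-age-group design (7/21/35 days, n = 5 per
group, groups W1/W3/W5) with two modification channels and, optionally,
treatment arms at the oldest age. Per site and sample:

* **Baselines.** A mixture concentrated near zero — Beta(1.0, 150) with a
  3% Beta(2, 12) methylated minority — reproduces a low global level
  (~2–3% read-weighted). Age-dynamic sites draw baselines from
  Beta(1.2, 45) (mean ≈ 2.6%): in a genome methylated at a few percent,
  drifting sites plausibly sit low, and on the logit scale an absolute
  drift at a low baseline is a large fold change, which is what makes age
  signal detectable at ~30X depth.
* **Clock (drift) sites** (default 10% of sites): slope drawn from
  N(1.32, 2.04²) % per week; the fraction follows a logistic path in age
  whose derivative at the midpoint age equals the nominal slope, evaluated
  at each sample's *effective* age. Fractions are clipped to
  [10⁻⁴, 1−10⁻⁴] with a logged count.
* **Entropy sites** (default 5%): per-sample fractions drawn from a Beta
  whose precision falls log-linearly with age (150 → 25) and whose mean
  moves toward 0.5 (35% of the distance by the oldest age). The mean
  shift is essential, not decorative: binary entropy is concave in the
  fraction, so lowering precision around a *fixed* mean can only lower
  expected entropy; only movement toward 0.5 inflates it.
* **Counts.** `n_valid ~ NegBin(mean 30, size 13)` — matching a reported
  depth of 32.6 ± 10.7X, overdispersed beyond Poisson — and
  `n_mod ~ Binomial(n_valid, p)`.
* **Treatment.** Purely an effective-age offset (a treated 35-day-old with
  Δ = 10 has the methylome of a 25-day-old), floored at 1 day. Mechanism-
  specific drug effects on particular pathways are not modelled.
* **Truth.** Drifting sites with nominal and realized (window-average)
  slopes, entropy sites, and per-sample effective ages are serialized to
  JSON alongside the bedMethyl fixtures.

Identical config (including seed) yields byte-identical outputs.

What the generator does **not** emulate: genome-scale site counts (10⁷–10⁸
sites; tests use 10²–10³ per channel), sequence context and neighbouring-
site correlation, basecalling/alignment error structure, strand or batch
effects, and covariates other than age and treatment. Passing tests
therefore demonstrate that the *statistical machinery* behaves correctly
under the declared generative model at the study's sample sizes and depth
— not that any particular biological dataset will reproduce specific
numbers.

## Problem sizes and runtime choices

Simulation-backed checks use 20 replicate cohorts of 2,000 sites per
channel (200 drifting) at 30X for recovery, error-control and
rejuvenation-detection properties, and 20 zero-signal cohorts of 150 sites
for permutation calibration (the null property does not depend on feature
count; the permutation test reruns nested training 101 times per cohort).
The pipeline's default permutation count is 100, matching the design it
emulates.

## Known limitations

* Pooled-count Fisher testing ignores between-replicate overdispersion;
  the per-replicate t-test option is the sensitivity check.
* Complete-case site intersection shrinks with cohort size; at much larger
  n a coverage-aware imputation strategy would be preferable.
* Clocks are strictly per-channel; 6mA/5mC integration is future work.
* The filtered mean ROC is a retained-subset statistic (see above) and
  should not be read as the genome-wide mean drift rate.
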