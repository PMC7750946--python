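# Methods

## The estimand and the design

The package targets the causal log-odds ratio of a binary disease
outcome per standard deviation of a continuous exposure, using genetic
variants as instrumental variables. A variant (or a weighted score over
variants) qualifies as an instrument when it (i) associates with the
exposure, (ii) is independent of outcome confounders, and (iii) affects
the outcome only through the exposure. Violations of (iii) — horizontal
pleiotropy — are the central threat, and the two-sample estimators
differ precisely in how they price it: IVW assumes none (fixed effects)
or balanced pleiotropy uncorrelated with instrument strength (random
effects); MR-Egger allows a systematic directional component, absorbed
by a free intercept; the weighted median tolerates up to half the
weight coming from invalid instruments.

## Generative model of the synthetic cohort

Genotypes: `m` independent biallelic variants, dosages
`g_ij ~ Binomial(2, f_j)` with effect-allele frequencies drawn uniformly
from `maf_range` (defaults 0.05–0.45). No linkage disequilibrium or
population structure is modelled — instruments are assumed pre-clumped,
as in a GWAS-derived weight file.

Exposure: `X = Σ_j γ_j g_j + c_x U + ε`, with `U ~ N(0,1)` a shared
confounder and `ε` sized so `Var(X) ≈ 1`. The raw `γ` draws are
rescaled so the *empirical* genetic variance fraction equals
`h2_exposure` exactly; the invariant `Var(Σγg)/Var(X) = h2 ± 0.005`
(checked at n = 10⁵) follows by construction.

Outcome: `Y ~ Bernoulli(logit⁻¹(α₀ + β X_std + c_y U + Σ_j α_j g_j))`,
where `X_std` is the standardized exposure (so `causal_beta` is per SD,
matching the reporting convention), `α_j` are per-variant pleiotropic
effects (zero / centred normal / half-normal for none / balanced /
directional, scale `pleiotropy_sd`), and `α₀` is calibrated by
bisection so the realized mean risk hits `baseline_prevalence` within
0.001 — a logistic intercept has no closed form under covariate
mixtures. The default prevalence is 0.09, the case fraction typical of
an EHR-derived reflux phenotype in a mid-life population cohort.

Coding model: a true case is coded positive with probability
`code_sensitivity`, a non-case with `1 − code_specificity`; coded-
positive individuals draw code families (self-report 1138, ICD10
K21.9/K21.0, OPCS4 G24/G25) from a conditional mixture with at least
one code guaranteed. Coded-negative individuals receive
acid-suppressant and endoscopy (G45) flags at configurable control
fractions, giving the stricter phenotype definitions something to
exclude. The mixture defaults were chosen so the four nested
definitions thin out roughly like a real flowchart (self-report
commonest, anti-reflux surgery rare); they are structural defaults, not
fitted quantities.

Relatedness: `n_relative_pairs` undirected third-degree-or-closer
pairs; a `chain_fraction` of pairs re-uses an already related
individual, producing the A–B/A–C chains that distinguish the greedy
maximum-relative-count rule from arbitrary pair-breaking.

Determinism: one global seed fans out to per-stage child seeds by fixed
offsets, so any stage re-run with the same config is byte-identical.

What the simulator does *not* emulate: LD between instruments,
population stratification, imputation uncertainty beyond a stored INFO
column, age-dependent incidence, or code dates (no incident/prevalent
distinction is generated; incident analyses take a caller-supplied
flag). Passing tests therefore validate the estimators and the pipeline
plumbing under clean instrument assumptions — not robustness to
stratification or LD.

## Phenotype definitions

Primary: case iff self-report 1138 ∪ ICD10 {K21.9, K21.0} ∪ OPCS4
{G24, G25}. SA1 drops cases whose only evidence is self-report and
excludes controls on acid suppressants or with a G45 endoscopy. SA2
additionally requires the erosive-oesophagitis code K21.0. SA3 keeps
only SA2-eligible cases with an anti-reflux operation code plus at
least one other confirming code (any of 1138/K21.9/K21.0). The case
sets nest by construction (SA3 ⊆ SA2 ⊆ SA1 ⊆ primary) and
`tabulate_flowchart` enforces the count monotonicity. Medication
exclusion consumes a boolean flag rather than drug code lists: mapping
drug names to classes is the caller's concern.

## Scores and estimators

Harmonization: where a weight file's effect/other alleles are swapped
relative to the dosage file, the dosage is recoded `g → 2−g`;
incompatible allele pairs are dropped with a warning; strand-ambiguous
(A/T, C/G) variants are retained with a warning by default (a strict
mode drops them). `Ws = Σβᵢ·SNPᵢ`; `WGRS = Ws·n/Σβᵢ` is invariant to
positive rescaling of the weights and equals the raw trait-raising
allele count when all weights are equal. Missing dosages are
mean-imputed to `2·eaf` (counted and flagged). The WGRS is deliberately
*not* re-standardized before IV analysis: affine score transformations
cancel in the two-stage estimator (covered by a property test).

Instrument strength: incremental R² of the score in an OLS of the
exposure, and the single-degree-of-freedom
`F = R²·(n−k−1)/(1−R²_full)`; F below 10 triggers a weak-instrument
warning.

One-sample two-stage IV: the exposure is inverse-normal transformed
(Blom offsets, `Φ⁻¹((r−3/8)/(m+1/4))`, ties sharing average ranks) so
estimates are per SD; stage 1 is OLS on the score plus covariates,
stage 2 a logistic fit on the stage-1 fitted values plus the same
covariates. The default SE is the stage-2 model's own — an
*uncorrected* two-stage SE that ignores stage-1 sampling error; it is
labelled as such in the results, and a seeded nonparametric bootstrap
is available. With instruments explaining ~2% of exposure variance the
first-stage contribution is small, and the coverage study (below)
shows near-nominal CI coverage under the default.

Two-sample estimators, from per-variant `(β̂_x, se_x, β̂_y, se_y)`
aligned to the same effect allele:

- Wald ratio `β̂_y/β̂_x`, first-order delta SE `se_y/|β̂_x|`
  (second-order terms omitted, matching the standard implementations).
- IVW: WLS of `β̂_y` on `β̂_x` through the origin with weights
  `1/se_y²` — algebraically the `β̂_x²/se_y²`-weighted mean of Wald
  ratios. Fixed-effects SE `(Σβ̂_x²/se_y²)^{-1/2}`; heterogeneity
  `Q = Σ w_j(θ_j − θ̂)²` in the ratio parameterization with
  `w_j = β̂_x_j²/se_y_j²`, df `k−1`; the multiplicative random-effects
  SE inflates by `√(max(1, Q/(k−1)))` (applied automatically once
  `Q > k−1` under `effects="auto"`).
- MR-Egger: variants oriented to `β̂_x > 0`, then WLS with a free
  intercept, weights `1/se_y²`. Slope = causal estimate; the intercept
  t-test (df `k−2`, residual dispersion estimated from the fit) tests
  directional pleiotropy. The dispersion is *not* floored at 1: flooring
  makes the intercept test conservative, and the estimated-scale t-test
  is exactly calibrated under the model (verified by simulation).
- Weighted median: Wald ratios ordered, weights `β̂_x²/se_y²`
  normalized; the estimate interpolates linearly where the centred
  cumulative weight crosses 1/2; SE by seeded parametric bootstrap
  (default B = 1000) redrawing `(β̂_x, β̂_y)` from their normal
  sampling distributions.

The per-variant scan behind the summary statistics is a plain
per-variant regression (linear for continuous traits, logistic for
binary), with a vectorised Newton solver across variants when no
covariates are requested; mixed-model association is out of scope.
Summary statistics may come from one cohort (overlapping samples — the
design flag records this, since weak-instrument bias then points toward
the confounded association) or two.

Per-unit rescaling: an OR per SD converts to an OR per `t` measurement
units via `exp(ln OR · t/units_per_sd)`; `units_per_sd` (e.g. cm of
waist circumference per SD of genetically predicted exposure) is an
input, not computed internally.

Power: `power = Φ(√(n·r²·cf·(1−cf))·|ln OR| − z_{1−α/2}) + Φ(−… −
z_{1−α/2})`, the normal approximation with the non-centrality of a
score-on-outcome logistic Wald test. Monotone in `n`, `r²`, `|ln OR|`
and case-fraction balance; degenerate inputs (`r² = 0`, OR = 1) return
α. Validated against a Monte-Carlo oracle (`mr_power_mc`) that
simulates cohorts and runs the same two-stage procedure, vectorised
across replicates.

## Validation studies and problem sizes

`refluxmr.validation` packages three replication studies (all seeded):

- **Coverage** (`coverage_study`): 100 replicates at n = 20 000, 50
  variants, h² = 0.02, causal OR 1.2, no pleiotropy. Because the
  logistic link makes marginal per-variant estimates non-collapsible
  and the one-cohort design adds weak-instrument overlap bias, the
  coverage target is the estimator's own large-sample value, estimated
  from an independent 100-replicate truth stream (separate seed
  offset) — not the generative constant. Both the two-stage IV and IVW
  CIs are then scored against that truth.
- **Null calibration** (`null_calibration`): 500 summary-level null
  replicates for the Egger intercept test (k = 20, weights exactly
  inverse-variance) and 500 cohort-level null replicates (n = 2 000,
  causal effect and pleiotropy zero, confounding present but
  independent of the score) for the GRS–outcome association.
- **Power grid** (`power_grid_check`): 12 points spanning
  n ∈ {5 000, 20 000}, r² ∈ {0.01, 0.02}, OR ∈ {1.0, 1.3, 1.6} at the
  cohort's 9% case fraction, 2 000 Monte-Carlo replicates per point.

These sizes keep the full suite and the acceptance script to a few
minutes on one CPU while leaving Monte-Carlo error well inside the
tolerances being checked.

## Numerical choices and degenerate inputs

- Prevalence calibration by Brent root-finding on the intercept,
  tolerance 10⁻³ on the mean risk.
- Ties in the greedy unrelated selection: the lowest id among
  maximum-degree individuals is removed (deterministic); once only
  disjoint simple pairs remain, one member of each is removed at random
  under the module seed. The equal-degree rule is a declared
  convention, not an inferred one.
- Filter boundaries are strict on the low side: INFO < 0.9 excluded,
  MAF < 0.1% excluded, p ≥ 5×10⁻⁸ excluded.
- `wald_ratio`/IVW with all `β̂_x = 0` raise; a single variant degrades
  IVW to the Wald ratio with a note; Egger and the weighted median
  require k ≥ 3.
- Perfect separation in logistic fits is flagged and the estimate
  withheld rather than reported.
- All-identical input to the inverse-normal transform raises (the
  transform is undefined); missing values pass through untouched.

## Known limitations

Uncorrected two-stage SEs are slightly anti-conservative in principle
(bootstrap available); the simulator's clean-instrument world cannot
reveal biases from LD, stratification or selection; the per-variant
scan is not a substitute for mixed-model association in structured
samples; and MR-PRESSO-style outlier removal and multivariable MR are
intentionally out of scope.
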