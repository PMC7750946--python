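# refluxmr

Causal inference for gastro-oesophageal reflux disease (GORD) from
biobank-style data: does central adiposity (or any other continuous
exposure) *cause* reflux disease, or are the observational associations
confounded?

`refluxmr` implements the full analysis pipeline as a tested, reusable
Python package, driven by its own synthetic cohort simulator so every
stage can be exercised — and validated against known ground truth —
without access to restricted individual-level biobank data:

1. **Synthetic biobank cohort** — per-individual SNP dosages under
   Hardy–Weinberg, a continuous exposure with a configurable genetic
   variance fraction, a shared confounder, a binary disease outcome
   generated on the log-odds scale (optionally with horizontal
   pleiotropy), EHR-style ICD10/OPCS4/self-report code lists, and planted
   close-relative pairs.
2. **QC** — greedy unrelated-subset selection (repeatedly removing the
   individual with the most relatives), and variant filters on
   imputation quality (INFO ≥ 0.9), minor-allele frequency (≥ 0.1%) and
   exposure-GWAS significance (p < 5×10⁻⁸).
3. **Phenotype derivation** — four nested GORD definitions from code
   lists (self-report 1138; ICD10 K21.9/K21.0; OPCS4 G24/G25), with
   control exclusions for acid-suppressant use and upper-GI endoscopy
   (G45).
4. **Weighted genetic risk scores** — allele harmonization, the weighted
   score `Ws = Σᵢ βᵢ·SNPᵢ`, its rescaling to the trait-raising-allele
   scale `WGRS = Ws·n/Σᵢβᵢ`, and instrument-strength diagnostics
   (incremental R², F).
5. **Observational associations** — rank-based inverse-normal (Blom)
   exposure transforms and age/sex-adjusted logistic models, so odds
   ratios read per SD of exposure.
6. **One-sample MR** — two-stage instrumental-variable estimation
   (stage 1: exposure ~ WGRS + covariates by OLS; stage 2: logistic
   outcome ~ fitted exposure + covariates), per-unit rescaling of per-SD
   odds ratios, and an analytic power calculation validated against a
   Monte-Carlo oracle.
7. **Two-sample MR** — per-variant association scans, Wald ratios
   `β̂_y/β̂_x`, and the inverse-variance-weighted (fixed/random effects
   with Cochran's Q), MR-Egger (free intercept as a directional-
   pleiotropy test) and weighted-median estimators.

The estimation API follows the statsmodels convention: a model object
built from data whose `fit()` returns a results object carrying
estimates, standard errors, confidence intervals, diagnostics and a
`summary()`.

## Worked example

```python
import numpy as np
import refluxmr as rm

cfg = rm.RunConfig()
cfg.sim.n_individuals = 20_000
cfg.sim.n_variants = 50
cfg.sim.h2_exposure = 0.02            # GRS explains 2% of exposure variance
cfg.sim.causal_beta = np.log(1.2)     # true OR 1.2 per SD of exposure
cfg.sim.code_sensitivity = 0.85
cfg.sim.code_specificity = 0.995
cfg.sim.seed = 7

results = rm.run_pipeline(cfg, "demo_run")
print(results["mr_one_sample"])
```

prints (from this exact configuration):

```
{'estimate': 0.30957, 'se': 0.18580, 'or': 1.3628,
 'or_ci95': [0.9469, 1.9616], 'p': 0.0957, 'stage1_F': 394.8, 'n': 19783}
```

Read: after removing one member of each related pair (19 783 of 20 000
retained), the weighted GRS is a strong instrument (stage-1 F ≈ 395,
incremental R² ≈ 0.02), and the two-stage IV estimate of the causal
odds ratio per SD of exposure is 1.36 (95% CI 0.95–1.96) — consistent
with the generative OR of 1.2 at this sample size, where the CI spans
roughly ±1.96×0.19 on the log scale. The same run writes a
`report.md` juxtaposing observational and MR estimates, the nested
phenotype flow counts, and a manifest with seeds and file digests.

The two-sample estimators work directly from summary statistics:

```python
from refluxmr import TwoSampleMR
model = TwoSampleMR(stats, design="one-cohort")   # beta_x/se_x/beta_y/se_y
print(model.summary())
```

A `refluxmr` command-line interface mirrors the stages
(`simulate`, `qc`, `derive`, `grs`, `observe`, `mr1`, `mr2`, `power`,
`rescale`, `run`); see `refluxmr --help`.

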