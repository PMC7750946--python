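"""Synthetic biobank-cohort simulator.

Generates cohorts with the statistical structure that instrumental-variable
analyses of a reflux-disease phenotype assume: independent biallelic
variants under Hardy-Weinberg equilibrium, a continuous exposure with a
known genetic variance fraction, a shared normal confounder acting on both
exposure and outcome, a binary outcome generated on the log-odds scale with
optional per-variant horizontal pleiotropy, diagnosis/procedure/self-report
code lists mapped from the latent disease state with configurable
sensitivity/specificity, and planted close-relative pairs.

Every stage is seeded from the global seed via fixed offsets, so re-running
any stage with the same config reproduces its output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import SimConfig, TrueParams

__all__ = [
    "Cohort",
    "simulate_genotypes",
    "simulate_exposure_outcome",
    "simulate_codes",
    "simulate_relatedness",
    "simulate_cohort",
]

# code labels emitted into the three coding families
SELF_REPORT_GORD = 1138
ICD10_CASE_CODES = ("K21.9", "K21.0")
OPCS4_CASE_CODES = ("G24", "G25")
OPCS4_ENDOSCOPY = "G45"

_BASES = np.array(list("ACGT"))


@dataclass
class Cohort:
    """Bundle of one simulated cohort: per-individual table, dosage matrix,
    per-variant metadata, relative pairs and the generative ground truth."""

    table: pd.DataFrame
    dosages: np.ndarray
    variants: pd.DataFrame
    pairs: pd.DataFrame
    true_params: TrueParams


def simulate_genotypes(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw an individuals x variants dosage matrix under Hardy-Weinberg.

    Each variant's effect-allele frequency is drawn uniformly from
    ``config.maf_range`` (a zero-width range fixes it); dosages are
    Binomial(2, maf). Returns the int8 dosage matrix and a variant table
    with allele labels, generative and empirical frequencies, and a
    simulated imputation-quality (INFO) column.
    """
    config.validate()
    rng = np.random.default_rng(config.child_seed("genotypes"))
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m) if hi > lo else np.full(m, lo)
    dosages = rng.binomial(2, maf, size=(n, m)).astype(np.int8)

    # allele labels: effect allele distinct from other allele
    ea_idx = rng.integers(0, 4, size=m)
    oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4
    info = np.round(np.clip(rng.beta(40, 1.5, size=m), 0.0, 1.0), 4)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{100000 + i}" for i in range(m)],
            "effect_allele": _BASES[ea_idx],
            "other_allele": _BASES[oa_idx],
            "maf": maf,
            "eaf": dosages.mean(axis=0) / 2.0,
            "info": info,
        }
    )
    return dosages, variants


def _simulate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Age/sex/centre/platform/PC covariates, independent of genotype."""
    cov = pd.DataFrame(
        {
            "age": rng.uniform(40, 70, size=n).round(1),
            "sex": rng.integers(0, 2, size=n),
            "centre": rng.integers(0, 10, size=n),
            "platform": (rng.random(n) < 0.1).astype(int),
        }
    )
    for k in range(1, 5):
        cov[f"pc{k}"] = rng.standard_normal(n)
    return cov


def simulate_exposure_outcome(
    config: SimConfig, dosages: np.ndarray
) -> tuple[pd.DataFrame, TrueParams]:
    """Generate the exposure, confounder, covariates and latent outcome.

    The exposure is X = sum_i gamma_i g_i + c_x U + eps with the gamma
    vector rescaled so the empirical genetic variance fraction equals
    ``h2_exposure``; U ~ N(0,1) is the shared confounder and the residual
    variance is set so Var(X) is approximately 1. The binary outcome is
    Bernoulli(expit(a0 + causal_beta * X_std + c_y U + sum_i alpha_i g_i))
    with the intercept a0 calibrated by root-finding so the realised mean
    risk matches ``baseline_prevalence`` to within 0.001.
    """
    config.validate()
    rng = np.random.default_rng(config.child_seed("exposure_outcome"))
    n, m = dosages.shape
    if n != config.n_individuals or m != config.n_variants:
        raise ValueError("dosage matrix shape does not match config")

    g = dosages.astype(float)
    h2 = config.h2_exposure
    gamma_raw = rng.normal(0.0, 1.0, size=m) * np.sqrt(1.0 / max(m, 1))
    if h2 > 0:
        genetic_raw = g @ gamma_raw
        sd_raw = genetic_raw.std()
        if sd_raw < 1e-12:
            raise RuntimeError(
                "h2 calibration failure: genetic component has zero variance "
                "(monomorphic variants or degenerate weights)"
            )
        gamma = gamma_raw * (np.sqrt(h2) / sd_raw)
    else:
        gamma = np.zeros(m)
    genetic = g @ gamma

    cx, cy = config.confounder_effect_x, config.confounder_effect_y
    u = rng.standard_normal(n)
    resid_var = 1.0 - h2 - cx**2
    x = genetic + cx * u + rng.normal(0.0, np.sqrt(resid_var), size=n)
    x_std = (x - x.mean()) / x.std()

    # per-variant pleiotropic outcome effects
    if config.pleiotropy_mode == "none" or config.pleiotropy_sd == 0.0:
        alpha = np.zeros(m)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=m)
    else:  # directional: half-normal, all raising risk
        alpha = np.abs(rng.normal(0.0, config.pleiotropy_sd, size=m))

    eta = config.causal_beta * x_std + cy * u + g @ alpha

    def mean_risk(a0: float) -> float:
        return float(expit(a0 + eta).mean()) - config.baseline_prevalence

    a0 = brentq(mean_risk, -30.0, 30.0, xtol=1e-4)
    p = expit(a0 + eta)
    if abs(p.mean() - config.baseline_prevalence) > 1e-3:
        raise RuntimeError("prevalence calibration failed to converge")
    latent_case = rng.random(n) < p

    table = _simulate_covariates(rng, n)
    table.insert(0, "iid", np.arange(n))
    table["confounder_u"] = u
    table["exposure"] = x
    table["latent_case"] = latent_case.astype(int)

    tp = TrueParams(
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        causal_beta=config.causal_beta,
        confounder_effect_x=cx,
        confounder_effect_y=cy,
        intercept=float(a0),
        maf=[float(v) for v in (np.atleast_1d(dosages.mean(axis=0) / 2.0))],
    )
    return table, tp


def simulate_codes(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Map the latent disease state to EHR-style code lists.

    A true case is coded positive with probability ``code_sensitivity``; a
    non-case with probability ``1 - code_specificity``. A coded-positive
    individual receives each case-defining code family with the
    ``code_mixture`` conditional probabilities (at least one is
    guaranteed). Coded-negative individuals receive acid-suppressant and
    upper-GI-endoscopy flags at the configured control fractions, so the
    stricter control definitions have something to exclude.
    """
    config.validate()
    if "latent_case" not in cohort.columns:
        raise ValueError("cohort lacks latent_case; run simulate_exposure_outcome")
    rng = np.random.default_rng(config.child_seed("codes"))
    n = len(cohort)
    case = cohort["latent_case"].to_numpy(dtype=bool)

    p_pos = np.where(case, config.code_sensitivity, 1.0 - config.code_specificity)
    coded = rng.random(n) < p_pos

    mix = config.code_mixture
    has = {fam: coded & (rng.random(n) < prob) for fam, prob in mix.items()}
    none = coded.copy()
    for v in has.values():
        none &= ~v
    has["self_1138"] = has.get("self_1138", np.zeros(n, bool)) | none

    out = cohort.copy()
    out["self_report_codes"] = [
        str(SELF_REPORT_GORD) if h else "" for h in has["self_1138"]
    ]
    icd = []
    for a, b in zip(has.get("icd_K21.9", np.zeros(n, bool)),
                    has.get("icd_K21.0", np.zeros(n, bool))):
        codes = [c for c, f in zip(ICD10_CASE_CODES, (a, b)) if f]
        icd.append(";".join(codes))
    out["icd10_codes"] = icd
    opcs = []
    for a, b in zip(has.get("opcs_G24", np.zeros(n, bool)),
                    has.get("opcs_G25", np.zeros(n, bool))):
        codes = [c for c, f in zip(OPCS4_CASE_CODES, (a, b)) if f]
        opcs.append(";".join(codes))
    out["opcs4_codes"] = opcs

    med = np.where(coded, rng.random(n) < 0.6,
                   rng.random(n) < config.med_control_fraction)
    endo = np.where(coded, rng.random(n) < 0.15,
                    rng.random(n) < config.endoscopy_control_fraction)
    out["on_acid_suppressant"] = med.astype(bool)
    out["had_endoscopy_g45"] = endo.astype(bool)
    return out


def simulate_relatedness(config: SimConfig) -> pd.DataFrame:
    """Plant undirected third-degree-or-closer relative pairs.

    With probability ``chain_fraction`` a new pair extends an already
    related individual (producing A-B, A-C chains that exercise the greedy
    maximum-relative-count removal rule); otherwise both members are drawn
    fresh. Pairs are distinct, undirected and never self-pairs.
    """
    config.validate()
    rng = np.random.default_rng(config.child_seed("relatedness"))
    n, k = config.n_individuals, config.n_relative_pairs
    rows: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    anchors: list[int] = []
    attempts = 0
    while len(rows) < k:
        attempts += 1
        if attempts > 100 * k + 1000:
            raise RuntimeError("could not place requested relative pairs")
        if anchors and rng.random() < config.chain_fraction:
            a = int(anchors[rng.integers(len(anchors))])
            b = int(rng.integers(n))
        else:
            a, b = (int(v) for v in rng.integers(n, size=2))
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        degree = int(rng.integers(1, 4))
        rows.append((key[0], key[1], degree))
        anchors.extend(key)
    return pd.DataFrame(rows, columns=["id1", "id2", "degree"])


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run all simulation stages and return the assembled cohort bundle."""
    dosages, variants = simulate_genotypes(config)
    table, tp = simulate_exposure_outcome(config, dosages)
    table = simulate_codes(table, config)
    pairs = simulate_relatedness(config)
    return Cohort(table=table, dosages=dosages, variants=variants,
                  pairs=pairs, true_params=tp)
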