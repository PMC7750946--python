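"""Weighted genetic risk scores and instrument-strength diagnostics.

A genetic risk score aggregates per-variant exposure effects into one
instrument. With per-allele weights b_i and dosages SNP_i in {0, 1, 2}:

    Ws   = sum_i b_i * SNP_i                 (raw weighted score)
    WGRS = Ws * n / sum_i b_i                (rescaled score)

The rescaling by the variant count n and the weight sum puts the score on
the trait-raising-allele-count scale: with all-equal weights WGRS is
exactly the allele count, and with all b_i >= 0 it lies in [0, 2n]. WGRS
is invariant to multiplying every weight by a positive constant.

Before scoring, the instrument table must be harmonized to the dosage
file's allele orientation: where effect/other alleles are swapped the
dosage is recoded g -> 2 - g so every weight applies to its own effect
allele. Instrument strength is summarised by the incremental R^2 of the
score in a linear model of the exposure and the corresponding single-
degree-of-freedom F statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HarmonizeResult",
    "harmonize",
    "weighted_score",
    "rescale_score",
    "instrument_strength",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

REQUIRED_WEIGHT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta")


def _check_instruments(instruments: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_WEIGHT_COLUMNS if c not in instruments.columns]
    if missing:
        raise ValueError(f"instrument table lacks columns: {missing}")
    if instruments["variant_id"].duplicated().any():
        dups = instruments.loc[
            instruments["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant_id in instrument table: {dups}")
    if not np.isfinite(instruments["beta"].to_numpy(float)).all():
        raise ValueError("non-finite beta in instrument table")
    if "se" in instruments.columns and (instruments["se"].to_numpy(float) <= 0).any():
        raise ValueError("instrument se must be > 0")


@dataclass
class HarmonizeResult:
    """Aligned instrument table plus the dosage orientation map."""

    instruments: pd.DataFrame          # rows aligned to the dosage file
    flip: pd.Series                    # True where dosage must be 2 - g
    ambiguous: pd.Series               # strand-ambiguous (A/T or C/G) variants
    dropped: list[str] = field(default_factory=list)

    @property
    def n_flipped(self) -> int:
        return int(self.flip.sum())


def harmonize(
    instruments: pd.DataFrame,
    variants: pd.DataFrame,
    strict_ambiguous: bool = False,
) -> HarmonizeResult:
    """Align an instrument-weight table to a dosage file's allele labels.

    Variants sharing an id must carry the same allele pair, possibly
    swapped; swapped entries get an orientation flip (dosage recoded
    g -> 2 - g when scoring). Incompatible allele pairs are dropped with a
    warning. Strand-ambiguous palindromic variants (A/T, C/G) are flagged
    and, under ``strict_ambiguous``, dropped.

    Harmonizing an already aligned table is the identity; the operation is
    idempotent.
    """
    _check_instruments(instruments)
    vmap = variants.set_index("variant_id")
    rows, flips, ambig, dropped = [], [], [], []
    for _, row in instruments.iterrows():
        vid = row["variant_id"]
        if vid not in vmap.index:
            dropped.append(vid)
            continue
        ref = vmap.loc[vid]
        ea, oa = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
        rea, roa = str(ref["effect_allele"]).upper(), str(ref["other_allele"]).upper()
        is_ambiguous = frozenset((ea, oa)) in AMBIGUOUS_PAIRS
        if (ea, oa) == (rea, roa):
            flip = False
        elif (ea, oa) == (roa, rea):
            flip = True
        else:
            dropped.append(vid)
            continue
        if is_ambiguous and strict_ambiguous:
            dropped.append(vid)
            continue
        rows.append(row)
        flips.append(flip)
        ambig.append(is_ambiguous)
    if dropped:
        warnings.warn(
            f"harmonize dropped {len(dropped)} variant(s): {dropped[:10]}",
            stacklevel=2,
        )
    if ambig and any(ambig) and not strict_ambiguous:
        warnings.warn(
            f"{sum(ambig)} strand-ambiguous variant(s) retained", stacklevel=2
        )
    aligned = pd.DataFrame(rows).reset_index(drop=True)
    return HarmonizeResult(
        instruments=aligned,
        flip=pd.Series(flips, dtype=bool),
        ambiguous=pd.Series(ambig, dtype=bool),
        dropped=dropped,
    )


def _oriented_dosages(
    dosages: np.ndarray | pd.DataFrame,
    instruments: pd.DataFrame,
    flip: pd.Series | None,
    eaf: np.ndarray | None,
) -> np.ndarray:
    """Column-select, orient and mean-impute the dosage matrix."""
    if isinstance(dosages, pd.DataFrame):
        missing_cols = [v for v in instruments["variant_id"]
                        if v not in dosages.columns]
        if missing_cols:
            raise ValueError(f"dosage file lacks variants: {missing_cols}")
        g = dosages[list(instruments["variant_id"])].to_numpy(float)
    else:
        g = np.asarray(dosages, float)
        if g.shape[1] != len(instruments):
            raise ValueError(
                "dosage matrix column count does not match instrument table"
            )
    if flip is not None:
        fl = flip.to_numpy(bool)
        g = np.where(fl[None, :], 2.0 - g, g)
    miss = np.isnan(g)
    if miss.any():
        all_missing = miss.all(axis=0)
        if all_missing.any():
            bad = instruments.loc[all_missing, "variant_id"].tolist()
            raise ValueError(f"variant(s) with all dosages missing: {bad}")
        if eaf is None:
            eaf = np.nanmean(g, axis=0) / 2.0
        fill = 2.0 * np.asarray(eaf, float)
        g = np.where(miss, fill[None, :], g)
        warnings.warn(
            f"{int(miss.sum())} missing dosage(s) imputed to 2*eaf", stacklevel=2
        )
    return g


def weighted_score(
    dosages: np.ndarray | pd.DataFrame,
    instruments: pd.DataFrame,
    flip: pd.Series | None = None,
    eaf: np.ndarray | None = None,
) -> np.ndarray:
    """Raw weighted score Ws = sum_i beta_i * SNP_i per individual.

    ``flip`` (from :func:`harmonize`) recodes swapped-orientation dosages;
    missing dosages are imputed to twice the effect-allele frequency.
    """
    _check_instruments(instruments)
    g = _oriented_dosages(dosages, instruments, flip, eaf)
    return g @ instruments["beta"].to_numpy(float)


def rescale_score(ws: np.ndarray, instruments: pd.DataFrame) -> np.ndarray:
    """Rescale Ws to the trait-raising-allele-count scale:
    WGRS = Ws * n / sum(beta)."""
    beta_sum = float(instruments["beta"].sum())
    if beta_sum == 0.0:
        raise ValueError("sum of instrument betas is zero; WGRS undefined")
    return np.asarray(ws, float) * len(instruments) / beta_sum


def instrument_strength(
    wgrs: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """Incremental R^2 and F statistic of the score on the exposure.

    Fits exposure ~ WGRS + covariates by OLS and reports the variance
    fraction uniquely attributable to the score together with the single-
    regressor F = R2_inc * (n - k - 1) / (1 - R2_full), its p-value, and
    the score's slope.
    """
    wgrs = np.asarray(wgrs, float)
    exposure = np.asarray(exposure, float)
    if np.std(wgrs) == 0:
        raise ValueError("constant score: instrument strength undefined")
    keep = np.isfinite(wgrs) & np.isfinite(exposure)
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        keep &= np.isfinite(cov).all(axis=1)
        cov = cov[keep]
    wgrs, exposure = wgrs[keep], exposure[keep]
    n = len(exposure)

    x_full = sm.add_constant(
        wgrs[:, None] if covariates is None else np.column_stack([wgrs, cov])
    )
    full = sm.OLS(exposure, x_full).fit()
    if covariates is None:
        r2_reduced = 0.0
    else:
        r2_reduced = sm.OLS(exposure, sm.add_constant(cov)).fit().rsquared
    r2_inc = full.rsquared - r2_reduced
    k = x_full.shape[1] - 1
    if full.rsquared >= 1.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = r2_inc * (n - k - 1) / (1.0 - full.rsquared)
        from scipy.stats import f as f_dist

        p = float(f_dist.sf(f_stat, 1, n - k - 1))
    return {
        "r2": float(r2_inc),
        "F": float(f_stat),
        "slope": float(full.params[1]),
        "p": p,
        "n": int(n),
    }
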