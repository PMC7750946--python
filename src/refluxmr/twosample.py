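"""Two-sample (summary-statistic) Mendelian randomization.

Given per-variant effect estimates on the exposure (beta_x, se_x) and on
the outcome (beta_y, se_y, log-odds scale), aligned to the same effect
allele, the per-variant causal estimate is the Wald ratio
beta_y / beta_x. Three combiners are provided:

IVW
    Weighted least squares of beta_y on beta_x through the origin with
    weights 1/se_y^2 — algebraically the inverse-variance-weighted mean of
    the Wald ratios with weights beta_x^2/se_y^2. Fixed-effects SE by
    default; after detecting heterogeneity (Cochran's Q over its df) a
    multiplicative random-effects model inflates the SE by
    sqrt(max(1, Q/(k-1))).
MR-Egger
    Weighted regression of beta_y on beta_x with an unconstrained
    intercept (variants oriented to beta_x > 0 first). The slope is the
    causal estimate; a non-zero intercept indicates directional
    horizontal pleiotropy.
Weighted median
    The 50% point of the weight-ordered Wald ratios (weights
    beta_x^2/se_y^2); consistent when at least half the weight comes from
    valid instruments. SE by seeded parametric bootstrap.

The per-variant association scan that produces the summary statistics is
a plain per-variant regression (linear for continuous traits, logistic
for binary), with a vectorised Newton solver when no covariates are
requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm, t as t_dist

from .observational import Z975

__all__ = [
    "MREstimate",
    "TwoSampleMR",
    "gwas_scan",
    "make_summary_stats",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
]

SUMMARY_COLUMNS = ("variant_id", "beta_x", "se_x", "beta_y", "se_y")


@dataclass
class MREstimate:
    """One causal estimate: log-OR per SD exposure with diagnostics."""

    method: str
    estimate: float
    se: float
    p: float
    n_variants: int
    q_statistic: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    effects: str | None = None
    note: str | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z975 * self.se, self.estimate + Z975 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))

    def format_or(self) -> str:
        lo, hi = self.or_ci95
        return f"{self.odds_ratio:.2f} ({lo:.2f}-{hi:.2f})"


def _check_stats(stats: pd.DataFrame, need_se_x: bool = False) -> pd.DataFrame:
    for c in ("beta_x", "beta_y", "se_y") + (("se_x",) if need_se_x else ()):
        if c not in stats.columns:
            raise ValueError(f"summary statistics lack column {c!r}")
    if (stats["se_y"].to_numpy(float) <= 0).any():
        raise ValueError("se_y must be > 0")
    if need_se_x and (stats["se_x"].to_numpy(float) < 0).any():
        raise ValueError("se_x must be >= 0")
    return stats


def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Per-variant causal estimate beta_y/beta_x with first-order
    (delta-method) standard error se_y/|beta_x|."""
    if beta_x == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    if se_y <= 0:
        raise ValueError("se_y must be > 0")
    return beta_y / beta_x, se_y / abs(beta_x)


def ivw(stats: pd.DataFrame, effects: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``effects``: 'fixed', 'random', or 'auto' (random once Q > k-1).
    A single variant degrades to the Wald ratio with a note.
    """
    stats = _check_stats(stats)
    bx = stats["beta_x"].to_numpy(float)
    by = stats["beta_y"].to_numpy(float)
    sy = stats["se_y"].to_numpy(float)
    k = len(bx)
    if k == 0:
        raise ValueError("no variants supplied")
    if np.all(bx == 0):
        raise ValueError("all beta_x are zero; IVW undefined")
    if k == 1:
        est, se = wald_ratio(bx[0], by[0], sy[0])
        p = float(2 * norm.sf(abs(est / se)))
        return MREstimate("IVW", est, se, p, 1, q_statistic=0.0, q_df=0,
                          effects="fixed",
                          note="single variant: reduces to the Wald ratio")

    w = bx**2 / sy**2                      # weights on the ratio scale
    nonzero = bx != 0
    ratios = np.zeros(k)
    ratios[nonzero] = by[nonzero] / bx[nonzero]
    est = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(bx**2 / sy**2)))
    q = float(np.sum(w[nonzero] * (ratios[nonzero] - est) ** 2))
    q_df = k - 1
    from scipy.stats import chi2

    q_p = float(chi2.sf(q, q_df))
    scale = float(np.sqrt(max(1.0, q / q_df)))
    if effects == "fixed":
        se, used = se_fixed, "fixed"
    elif effects == "random":
        se, used = se_fixed * scale, "random"
    elif effects == "auto":
        if q > q_df:
            se, used = se_fixed * scale, "random"
        else:
            se, used = se_fixed, "fixed"
    else:
        raise ValueError("effects must be 'fixed', 'random' or 'auto'")
    p = float(2 * norm.sf(abs(est / se)))
    return MREstimate("IVW", est, float(se), p, k, q_statistic=q, q_df=q_df,
                      q_pvalue=q_p, effects=used)


def egger(stats: pd.DataFrame) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_y on beta_x with a free
    intercept, after orienting every variant to beta_x > 0.

    Slope = causal estimate; the intercept and its p-value test
    directional pleiotropy (t-test on k-2 df, residual dispersion
    estimated from the fit).
    """
    stats = _check_stats(stats)
    bx = stats["beta_x"].to_numpy(float).copy()
    by = stats["beta_y"].to_numpy(float).copy()
    sy = stats["se_y"].to_numpy(float)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    flip = bx < 0
    bx[flip], by[flip] = -bx[flip], -by[flip]
    design = sm.add_constant(bx)
    fit = sm.WLS(by, design, weights=1.0 / sy**2).fit()
    df = k - 2
    est, se = float(fit.params[1]), float(fit.bse[1])
    icpt, icpt_se = float(fit.params[0]), float(fit.bse[0])
    p = float(2 * t_dist.sf(abs(est / se), df))
    icpt_p = float(2 * t_dist.sf(abs(icpt / icpt_se), df))
    return MREstimate("MR-Egger", est, se, p, k,
                      intercept=icpt, intercept_se=icpt_se, intercept_p=icpt_p,
                      effects="multiplicative dispersion")


def weighted_median(stats: pd.DataFrame, bootstrap_B: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimate of the causal effect.

    Wald ratios are ordered; with weights beta_x^2/se_y^2 normalized to
    sum 1, the estimate interpolates the ratio at which the centred
    cumulative weight crosses one half. Consistent when valid instruments
    carry at least 50% of the weight. SE from ``bootstrap_B`` seeded
    parametric bootstrap draws of (beta_x, beta_y).
    """
    stats = _check_stats(stats)
    bx = stats["beta_x"].to_numpy(float)
    by = stats["beta_y"].to_numpy(float)
    sy = stats["se_y"].to_numpy(float)
    sx = stats["se_x"].to_numpy(float) if "se_x" in stats.columns \
        else np.zeros_like(bx)
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median requires at least 3 variants")
    if np.any(bx == 0):
        raise ValueError("beta_x = 0 makes a Wald ratio undefined")

    est = _weighted_median_point(by / bx, bx**2 / sy**2)
    rng = np.random.default_rng(seed)
    draws = np.empty(bootstrap_B)
    for b in range(bootstrap_B):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        draws[b] = _weighted_median_point(
            bys[ok] / bxs[ok], bxs[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(draws, ddof=1))
    p = float(2 * norm.sf(abs(est / se))) if se > 0 else np.nan
    return MREstimate("weighted median", float(est), se, p, k,
                      note=f"bootstrap B={bootstrap_B}")


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("non-positive total weight")
    w = w / total
    cum = np.cumsum(w) - 0.5 * w          # centred cumulative weight
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5)) - 1
    frac = (0.5 - cum[j]) / (cum[j + 1] - cum[j])
    return float(r[j] + frac * (r[j + 1] - r[j]))


class TwoSampleMR:
    """Summary-statistic MR model over an aligned per-variant table.

    Parameters
    ----------
    stats : DataFrame
        Columns beta_x, se_x, beta_y, se_y (plus variant_id), all aligned
        to the same effect allele per variant.
    design : str
        'one-cohort' when exposure and outcome associations come from the
        same individuals (sample overlap; weak-instrument bias acts
        toward the observational estimate) or 'two-cohort' for
        non-overlapping samples. Recorded in the results.
    """

    METHODS = ("ivw", "egger", "weighted_median")

    def __init__(self, stats: pd.DataFrame, design: str = "one-cohort"):
        if design not in ("one-cohort", "two-cohort"):
            raise ValueError("design must be 'one-cohort' or 'two-cohort'")
        self.stats = _check_stats(stats.reset_index(drop=True))
        self.design = design
        self.n_variants = len(self.stats)

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        if method == "ivw":
            res = ivw(self.stats, **kwargs)
        elif method == "egger":
            res = egger(self.stats, **kwargs)
        elif method == "weighted_median":
            res = weighted_median(self.stats, **kwargs)
        else:
            raise ValueError(f"unknown method {method!r}")
        res.note = (res.note + "; " if res.note else "") + f"design={self.design}"
        return res

    def fit_all(self, seed: int = 0) -> dict[str, MREstimate]:
        out = {"ivw": self.fit("ivw")}
        if self.n_variants >= 3:
            out["egger"] = self.fit("egger")
            out["weighted_median"] = self.fit("weighted_median", seed=seed)
        return out

    def summary(self, seed: int = 0) -> str:
        lines = [
            "Two-sample Mendelian randomization "
            f"({self.n_variants} variants, {self.design})",
            f"{'method':<18}{'OR (95% CI)':<22}{'p':<12}{'Q (df)':<14}"
            "intercept (p)",
        ]
        for res in self.fit_all(seed=seed).values():
            q = (f"{res.q_statistic:.2f} ({res.q_df})"
                 if res.q_statistic is not None else "-")
            icpt = (f"{res.intercept:.4f} ({res.intercept_p:.3f})"
                    if res.intercept is not None else "-")
            lines.append(
                f"{res.method:<18}{res.format_or():<22}{res.p:<12.3g}"
                f"{q:<14}{icpt}"
            )
        return "\n".join(lines)


def gwas_scan(
    dosages: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    trait_type: str = "continuous",
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant association scan: one regression per variant.

    Linear regression for continuous traits, logistic (log-odds betas)
    for binary. Betas are per effect-allele dosage. Monomorphic variants
    are dropped with a flag column. Without covariates both paths are
    fully vectorised across variants; with covariates each variant is fit
    through statsmodels.
    """
    g = np.asarray(dosages, float)
    y = np.asarray(trait, float)
    n, m = g.shape
    if trait_type not in ("continuous", "binary"):
        raise ValueError("trait_type must be 'continuous' or 'binary'")
    ids = variant_ids if variant_ids is not None \
        else [f"v{j}" for j in range(m)]
    mono = g.std(axis=0) == 0

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    if covariates is None:
        cols = ~mono
        if trait_type == "continuous":
            b, s = _linear_scan(g[:, cols], y)
        else:
            b, s = _logistic_scan(g[:, cols], y)
        beta[cols], se[cols] = b, s
    else:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(m):
            if mono[j]:
                continue
            design = sm.add_constant(np.column_stack([g[:, j], cov]))
            if trait_type == "continuous":
                fit = sm.OLS(y, design).fit()
            else:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            beta[j], se[j] = float(fit.params[1]), float(fit.bse[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2 * norm.sf(np.abs(beta / se))
    out = pd.DataFrame(
        {"variant_id": ids, "beta": beta, "se": se, "p": p,
         "monomorphic": mono}
    )
    return out[~out["monomorphic"]].reset_index(drop=True)


def _linear_scan(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Simple-regression slope and SE for every column of g at once."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    beta = gc.T @ yc / sxx
    # residual variance per variant: SSE = Syy - beta^2 Sxx
    syy = float((yc**2).sum())
    sse = syy - beta**2 * sxx
    sigma2 = sse / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def _logistic_scan(
    g: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Newton-Raphson for per-variant intercept+slope logistic
    regressions; returns slope and its Wald SE per variant."""
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) != 2:
        raise ValueError("binary trait must contain both classes")
    n, m = g.shape
    a = np.full(m, float(np.log(y.mean() / (1 - y.mean()))))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        p = expit(eta)
        w = p * (1 - p)
        resid = (y[:, None] - p)
        g0 = resid.sum(axis=0)
        g1 = (resid * g).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g**2).sum(axis=0)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        a, b = a + da, b + db
        if np.nanmax(np.abs(np.concatenate([da, db]))) < tol:
            break
    eta = a[None, :] + g * b[None, :]
    w = expit(eta) * (1 - expit(eta))
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g**2).sum(axis=0)
    det = h00 * h11 - h01**2
    se = np.sqrt(h00 / det)
    return b, se


def make_summary_stats(
    exposure_scan: pd.DataFrame, outcome_scan: pd.DataFrame
) -> pd.DataFrame:
    """Merge an exposure scan and an outcome scan (same effect alleles)
    into the aligned summary-statistic table the estimators consume."""
    merged = exposure_scan.merge(
        outcome_scan, on="variant_id", suffixes=("_x", "_y"), how="inner"
    )
    out = merged[["variant_id", "beta_x", "se_x", "beta_y", "se_y"]].copy()
    if "p_x" in merged.columns:
        out["p_x"] = merged["p_x"]
    if "p_y" in merged.columns:
        out["p_y"] = merged["p_y"]
    return out
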