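"""Observational associations between exposures and case/control status.

Continuous exposures are rank-based inverse-normal transformed (Blom
offsets) before modelling, so odds ratios read "per SD" of the exposure.
Associations are covariate-adjusted maximum-likelihood logistic fits;
results carry the log-odds estimate, its Wald standard error, 95% CI and
p-value, and the number of complete cases actually used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

__all__ = ["AssocResult", "inverse_normal", "logistic_assoc", "summarize_cohort"]

Z975 = 1.959963984540054


@dataclass
class AssocResult:
    """One fitted association: log-OR (or slope), SE, CI, p and metadata."""

    estimate: float
    se: float
    p: float
    n_used: int
    model: str
    converged: bool = True
    separation: bool = False

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


def inverse_normal(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Non-missing entries are mapped to Phi^{-1}((r - 3/8) / (m + 1/4))
    where r is the average rank (ties share ranks) and m the number of
    non-missing values; missing entries stay missing. All-identical input
    is rejected as the transform is undefined there.
    """
    x = np.asarray(values, float)
    out = np.full_like(x, np.nan, dtype=float)
    mask = np.isfinite(x)
    m = int(mask.sum())
    if m < 2:
        raise ValueError("inverse_normal needs at least 2 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("inverse_normal undefined for all-identical input")
    ranks = rankdata(obs, method="average")
    out[mask] = norm.ppf((ranks - 0.375) / (m + 0.25))
    return out


def logistic_assoc(
    outcome: np.ndarray | pd.Series,
    predictor: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> AssocResult:
    """Covariate-adjusted logistic regression of a binary outcome on one
    predictor; complete-case analysis.

    The reported estimate is the predictor's log-odds coefficient. Perfect
    separation is flagged and the estimate withheld (NaN).
    """
    y = np.asarray(outcome, float)
    x = np.asarray(predictor, float)
    keep = np.isfinite(y) & np.isfinite(x)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        keep &= np.isfinite(cov).all(axis=1)
        cov = cov[keep]
    y, x = y[keep], x[keep]
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) != 2:
        raise ValueError("outcome must be binary with both classes present")

    design = sm.add_constant(
        x[:, None] if cov is None else np.column_stack([x, cov])
    )
    model_desc = f"logit(outcome) ~ predictor + {0 if cov is None else cov.shape[1]} covariate(s)"
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return AssocResult(np.nan, np.nan, np.nan, int(keep.sum()),
                           model_desc, converged=False, separation=True)
    se = float(fit.bse[1])
    separated = (not fit.mle_retvals.get("converged", True)) or not np.isfinite(se) \
        or se > 1e3
    if separated:
        return AssocResult(np.nan, np.nan, np.nan, int(keep.sum()),
                           model_desc, converged=False, separation=True)
    return AssocResult(
        estimate=float(fit.params[1]),
        se=se,
        p=float(fit.pvalues[1]),
        n_used=int(len(y)),
        model=model_desc,
    )


def two_by_two_or(a: int, b: int, c: int, d: int) -> AssocResult:
    """Crude odds ratio from a 2x2 table.

    ``a``/``b`` are exposed cases/controls, ``c``/``d`` unexposed
    cases/controls; the estimate is log(ad/bc) with the Woolf standard
    error sqrt(1/a + 1/b + 1/c + 1/d). Identical to an unadjusted
    logistic fit of case status on the exposure indicator.
    """
    if min(a, b, c, d) <= 0:
        raise ValueError("all four cell counts must be positive")
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = log_or / se
    p = float(2 * norm.sf(abs(z)))
    return AssocResult(log_or, se, p, a + b + c + d, "2x2 cross-product")


def summarize_cohort(
    cohort: pd.DataFrame,
    status: pd.Series | np.ndarray,
    traits: list[str],
    covariate_cols: list[str] = ("age", "sex"),
    binary_traits: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Demographics-style table: per-trait summaries by case status with a
    covariate-adjusted odds ratio per trait.

    Continuous traits are shown as mean +/- SD and are inverse-normal
    transformed before the logistic fit so the OR is per SD; binary traits
    are shown as count (%). A trait listed among the covariates is
    adjusted only for the remaining covariates.
    """
    is_case = np.asarray(status) == "case" if np.asarray(status).dtype.kind in "OU" \
        else np.asarray(status).astype(bool)
    rows = []
    for trait in traits:
        vals = cohort[trait]
        is_binary = trait in binary_traits or set(
            pd.unique(vals.dropna())) <= {0, 1, True, False}
        adj = [c for c in covariate_cols if c != trait]
        cov = cohort[adj] if adj else None
        if is_binary:
            pred = vals.astype(float).to_numpy()
            desc_ctrl = _pct(vals[~is_case])
            desc_case = _pct(vals[is_case])
        else:
            pred = inverse_normal(vals)
            desc_ctrl = _mean_sd(vals[~is_case])
            desc_case = _mean_sd(vals[is_case])
        res = logistic_assoc(is_case.astype(float), pred, cov)
        rows.append(
            {
                "trait": trait,
                "controls": desc_ctrl,
                "cases": desc_case,
                "n_used": res.n_used,
                "odds_ratio": res.format_or() if res.converged else "NA",
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def _mean_sd(s: pd.Series) -> str:
    v = s.dropna()
    if len(v) == 0:
        return "0"
    return f"{v.mean():.2f} ± {v.std():.2f}"


def _pct(s: pd.Series) -> str:
    v = s.dropna().astype(float)
    if len(v) == 0:
        return "0 (0%)"
    return f"{int(v.sum())} ({100 * v.mean():.2f}%)"
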