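"""Configuration objects for the synthetic cohort simulator and the pipeline.

The simulator emulates the statistical structure of a large genotyped
population cohort with linked hospital-episode coding: per-individual SNP
dosages, continuous adiposity-style exposures, a binary reflux-disease
outcome derived from diagnosis/procedure/self-report codes, shared
confounding, optional horizontal pleiotropy, and close-relative pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["SimConfig", "TrueParams", "RunConfig"]


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort.

    Parameters
    ----------
    n_individuals : int
        Cohort size (>= 2).
    n_variants : int
        Number of independent biallelic instrument variants.
    maf_range : tuple of float
        Inclusive bounds for per-variant minor-allele frequencies, within
        (0, 0.5]. A zero-width range fixes every MAF.
    h2_exposure : float
        Fraction of exposure variance explained by the genetic component
        (the instrument strength on the variance scale).
    confounder_effect_x : float
        Slope of the latent confounder U ~ N(0,1) on the exposure, per SD.
    confounder_effect_y : float
        Log-odds effect of U on the outcome, per SD.
    causal_beta : float
        Causal log-odds ratio of the outcome per SD of exposure.
    pleiotropy_mode : str
        'none', 'balanced' (per-variant outcome effects centred at zero) or
        'directional' (half-normal, all one sign).
    pleiotropy_sd : float
        Scale of the per-allele pleiotropic log-OR distribution.
    baseline_prevalence : float
        Target marginal case fraction; the logistic intercept is calibrated
        by bisection to hit it within +/- 0.001.
    code_sensitivity, code_specificity : float
        Probability a true case receives at least one case-defining code,
        and that a non-case receives none.
    n_relative_pairs : int
        Number of third-degree-or-closer relative pairs to plant.
    chain_fraction : float
        Fraction of planted pairs that extend an existing related
        individual into a chain (A-B, A-C), exercising the greedy rule.
    med_control_fraction : float
        Fraction of coded controls flagged as taking acid-suppressant
        medication (proton-pump inhibitors / H2 blockers).
    endoscopy_control_fraction : float
        Fraction of coded controls with an upper-GI endoscopy code (G45).
    code_mixture : dict
        Conditional probabilities, given an individual is coded positive,
        of carrying each case-defining code family. At least one code is
        guaranteed (fallback to self-report).
    seed : int
        Global seed; per-stage child seeds are derived by fixed offsets.
    """

    n_individuals: int = 20_000
    n_variants: int = 50
    maf_range: tuple[float, float] = (0.05, 0.45)
    h2_exposure: float = 0.02
    confounder_effect_x: float = 0.3
    confounder_effect_y: float = 0.3
    causal_beta: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    baseline_prevalence: float = 0.09
    code_sensitivity: float = 1.0
    code_specificity: float = 1.0
    n_relative_pairs: int = 0
    chain_fraction: float = 0.3
    med_control_fraction: float = 0.12
    endoscopy_control_fraction: float = 0.05
    code_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "self_1138": 0.62,
            "icd_K21.9": 0.45,
            "icd_K21.0": 0.30,
            "opcs_G24": 0.030,
            "opcs_G25": 0.004,
        }
    )
    seed: int = 0

    # fixed offsets fanning the global seed out to per-stage streams
    _SEED_OFFSETS = {
        "genotypes": 11,
        "exposure_outcome": 23,
        "codes": 37,
        "relatedness": 53,
    }

    def child_seed(self, stage: str) -> int:
        if stage not in self._SEED_OFFSETS:
            raise KeyError(f"unknown simulation stage: {stage!r}")
        return (int(self.seed) + self._SEED_OFFSETS[stage]) % (2**31 - 1)

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in (
            "h2_exposure",
            "code_sensitivity",
            "code_specificity",
            "chain_fraction",
            "med_control_fraction",
            "endoscopy_control_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(
                "pleiotropy_mode must be 'none', 'balanced' or 'directional'"
            )
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if self.n_relative_pairs < 0:
            raise ValueError("n_relative_pairs must be >= 0")
        max_pairs = self.n_individuals * (self.n_individuals - 1) // 2
        if self.n_relative_pairs > max_pairs:
            raise ValueError(
                f"n_relative_pairs={self.n_relative_pairs} exceeds the "
                f"{max_pairs} distinct pairs available"
            )
        if self.h2_exposure + self.confounder_effect_x**2 >= 1.0:
            raise ValueError(
                "h2_exposure + confounder_effect_x**2 must be < 1 so the "
                "residual exposure variance is positive"
            )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class TrueParams:
    """Ground-truth generative parameters stored for oracle checks.

    gamma : per-variant allele -> exposure slopes (after h2 calibration)
    alpha : per-variant pleiotropic allele -> outcome log-ORs (zero when
            pleiotropy_mode == 'none')
    causal_beta : outcome log-OR per SD of exposure
    confounder_effect_x / _y : confounder slopes as in SimConfig
    intercept : calibrated logistic intercept
    maf : per-variant generative minor-allele frequencies
    """

    gamma: list[float]
    alpha: list[float]
    causal_beta: float
    confounder_effect_x: float
    confounder_effect_y: float
    intercept: float
    maf: list[float]

    def validate(self, n_variants: int, pleiotropy_mode: str = "none") -> None:
        if not (len(self.gamma) == len(self.alpha) == len(self.maf) == n_variants):
            raise ValueError("per-variant parameter lengths must equal n_variants")
        if pleiotropy_mode == "none" and any(a != 0.0 for a in self.alpha):
            raise ValueError("alpha must be all-zero when pleiotropy_mode='none'")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrueParams":
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> QC -> derive ->
    GRS -> observational -> one-sample MR -> two-sample MR -> report)."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "qc": True,
            "derive": True,
            "grs": True,
            "observational": True,
            "mr_one_sample": True,
            "mr_two_sample": True,
            "report": True,
        }
    )
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    sensitivity_levels: list[int] = field(default_factory=lambda: [1, 2, 3])
    out_dir: str = "refluxmr_run"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(raw.get("sim", {}))
        cfg = cls(sim=sim)
        if "stages" in raw:
            unknown = set(raw["stages"]) - set(cfg.stages)
            if unknown:
                raise ValueError(f"unknown stages: {sorted(unknown)}")
            cfg.stages.update(raw["stages"])
        cfg.covariates = list(raw.get("covariates", cfg.covariates))
        cfg.sensitivity_levels = [int(x) for x in raw.get(
            "sensitivity_levels", cfg.sensitivity_levels)]
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        return cfg
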