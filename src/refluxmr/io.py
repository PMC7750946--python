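"""Readers and writers for the pipeline's tab-separated interchange files.

Formats:
  cohort table    one row per individual, TSV
  dosage matrix   TSV, header row of variant IDs, one row per individual
  variant table   TSV: variant_id, effect_allele, other_allele, eaf, info, p
  pairs file      TSV: id1, id2 (optional degree)
  weight file     TSV: variant_id, effect_allele, other_allele, beta, se, p, trait
  summary stats   TSV: variant_id, effect_allele, beta_x, se_x, p_x,
                  beta_y, se_y, p_y
  ground truth    JSON
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TrueParams
from .qc import VariantRecord

WEIGHT_HEADER = ["variant_id", "effect_allele", "other_allele",
                 "beta", "se", "p", "trait"]


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


_CODE_COLS = ("self_report_codes", "icd10_codes", "opcs4_codes")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _CODE_COLS})
    for col in _CODE_COLS:
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_dosages(dosages: np.ndarray, variant_ids, path) -> None:
    pd.DataFrame(dosages, columns=list(variant_ids)).to_csv(
        path, sep="\t", index=False)


def read_dosages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def variant_records(variants: pd.DataFrame,
                    p_col: str = "p") -> list[VariantRecord]:
    """Variant table rows as validated VariantRecord objects."""
    records = []
    for _, r in variants.iterrows():
        rec = VariantRecord(
            variant_id=str(r["variant_id"]),
            effect_allele=str(r["effect_allele"]),
            other_allele=str(r["other_allele"]),
            eaf=float(r["eaf"]),
            info=float(r.get("info", 1.0)),
            p_exposure=float(r.get(p_col, 0.0)),
        )
        records.append(rec)
    return records


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_true_params(tp: TrueParams, path) -> None:
    Path(path).write_text(json.dumps(tp.to_dict(), indent=1))


def read_true_params(path) -> TrueParams:
    return TrueParams.from_dict(json.loads(Path(path).read_text()))


def write_weights(weights: pd.DataFrame, path) -> None:
    cols = [c for c in WEIGHT_HEADER if c in weights.columns]
    weights[cols].to_csv(path, sep="\t", index=False)


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WEIGHT_HEADER[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"weight file lacks required columns: {missing}")
    return df


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("variant_id", "beta_x", "se_y", "beta_y"):
        if c not in df.columns:
            raise ValueError(f"summary-statistics file lacks column {c!r}")
    return df
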