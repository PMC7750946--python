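"""Sample- and variant-level quality control.

Implements the greedy unrelated-subset rule used when pruning a cohort to
unrelated individuals (repeatedly removing whoever currently has the most
third-degree-or-closer relatives, so as many individuals as possible are
retained), and the standard instrument-variant filters on imputation
quality (INFO), minor-allele frequency and exposure-GWAS p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["VariantRecord", "select_unrelated", "filter_variants"]


@dataclass
class VariantRecord:
    """One biallelic variant with the metadata the filters consume."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    info: float
    p_exposure: float

    def validate(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: alleles must differ")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf must lie in (0, 1)")
        if not (0.0 <= self.info <= 1.0):
            raise ValueError(f"{self.variant_id}: info must lie in [0, 1]")
        if not (0.0 <= self.p_exposure <= 1.0):
            raise ValueError(f"{self.variant_id}: p must lie in [0, 1]")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


def select_unrelated(
    individual_ids: Iterable,
    related_pairs: Iterable[tuple],
    seed: int = 0,
) -> set:
    """Greedy unrelated-subset selection.

    While related pairs remain, the individual with the current maximum
    number of relatives is removed (if A is related to B and C but B and C
    are unrelated, A goes). Ties among equal-count individuals are broken
    by lowest id for determinism. When only simple pairs remain (everyone
    has exactly one relative), one member of each pair is removed at
    random, driven by ``seed``.

    Returns the retained id set; with no pairs everyone is retained.
    """
    ids = set(individual_ids)
    adj: dict = {}
    for pair in related_pairs:
        a, b = pair[0], pair[1]
        if a not in ids or b not in ids:
            raise ValueError(f"pair ({a}, {b}) references unknown individual ids")
        if a == b:
            raise ValueError(f"self-pair for id {a}")
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    rng = np.random.default_rng(seed)
    retained = set(ids)

    def drop(v) -> None:
        retained.discard(v)
        for w in adj.pop(v, ()):  # noqa: B905
            adj[w].discard(v)
            if not adj[w]:
                del adj[w]

    while adj:
        max_deg = max(len(nbrs) for nbrs in adj.values())
        if max_deg > 1:
            victim = min(v for v, nbrs in adj.items() if len(nbrs) == max_deg)
            drop(victim)
        else:
            # only disjoint simple pairs remain: random member of each goes
            for a in sorted(adj):
                if a not in adj:
                    continue
                b = next(iter(adj[a]))
                drop(a if rng.random() < 0.5 else b)
    return retained


def filter_variants(
    variants: Sequence[VariantRecord],
    info_min: float = 0.9,
    maf_min: float = 0.001,
    p_max: float = 5e-8,
) -> list[VariantRecord]:
    """Keep variants with INFO >= info_min, MAF >= maf_min and
    exposure p-value strictly below p_max; input order is preserved.

    Exclusion is strict on the low side (INFO < 0.9 excluded, MAF < 0.1%
    excluded) and the significance cut is strict (p < 5e-8 kept), matching
    the usual genome-wide instrument-selection convention. Malformed
    records raise with the offending variant_id.
    """
    kept = []
    for v in variants:
        v.validate()
        if v.info >= info_min and v.maf >= maf_min and v.p_exposure < p_max:
            kept.append(v)
    return kept
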