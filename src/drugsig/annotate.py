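"""Functional annotation of signature genes.

Two analyses: (1) mapping drug targets x signature genes onto a curated
list of synthetic-lethality (SL) and synthetic-dosage-lethality (SDL) gene
pairs — a pair matches a drug when its A gene is among the drug's targets
and its B gene is in the signature set; (2) one-sided hypergeometric
enrichment of a gene set collection (GMT) in a query gene list, with
significance requiring both p < p_cutoff and an overlap strictly greater
than min_overlap genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "SLPair",
    "SLMapping",
    "EnrichmentResult",
    "read_sl_pairs",
    "map_sl_pairs",
    "hypergeometric_enrichment",
]

INTERACTIONS = ("SL", "SDL")


@dataclass(frozen=True)
class SLPair:
    """Ordered gene pair: inactivation (SL) or over-activity (SDL) of
    gene_a makes gene_b essential."""

    gene_a: str
    gene_b: str
    interaction: str

    def __post_init__(self) -> None:
        if self.interaction not in INTERACTIONS:
            raise ValueError(f"interaction must be one of {INTERACTIONS}")
        if self.gene_a == self.gene_b:
            raise ValueError("gene_a and gene_b must differ")


@dataclass
class SLMapping:
    per_drug: dict[str, list[SLPair]]
    nonredundant: dict[str, set[SLPair]]  # interaction -> distinct pairs
    contributing_drugs: dict[str, set[str]]  # interaction -> drugs with >=1 match

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            it: {"pairs": len(self.nonredundant.get(it, ())),
                 "drugs": len(self.contributing_drugs.get(it, ()))}
            for it in INTERACTIONS
        }


def read_sl_pairs(path: str | Path) -> list[SLPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_a", "gene_b", "interaction"}
    if need - set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    pairs = [SLPair(r.gene_a, r.gene_b, r.interaction) for r in df.itertuples()]
    if len(set(pairs)) != len(pairs):
        raise ValueError(f"{path}: duplicate pair records")
    return pairs


def map_sl_pairs(
    drug_targets: Mapping[str, Iterable[str]],
    signature_genes: Iterable[str],
    pairs: Iterable[SLPair],
) -> SLMapping:
    """Match SL/SDL pairs whose A gene is a drug target and B gene a signature gene.

    Returns per-drug matched pairs plus, per interaction type, the
    non-redundant pair set and the set of contributing drugs.
    """
    sig = set(signature_genes)
    pairs = list(pairs)
    per_drug: dict[str, list[SLPair]] = {}
    nonred: dict[str, set[SLPair]] = {it: set() for it in INTERACTIONS}
    contrib: dict[str, set[str]] = {it: set() for it in INTERACTIONS}
    for drug in sorted(drug_targets):
        targets = set(drug_targets[drug])
        matched = [p for p in pairs if p.gene_a in targets and p.gene_b in sig]
        per_drug[drug] = matched
        for p in matched:
            nonred[p.interaction].add(p)
            contrib[p.interaction].add(drug)
    return SLMapping(per_drug, nonred, contrib)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int
    overlap_genes: frozenset[str]
    p_value: float
    significant: bool
    set_size: int = 0
    extra: dict = field(default_factory=dict)


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    p_cutoff: float = 0.05,
    min_overlap: int = 2,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per gene set.

    p is the upper-tail probability of observing at least the seen overlap
    when |query| genes are drawn from the universe without replacement.
    A set is significant when p < p_cutoff AND overlap > min_overlap
    (strictly more than ``min_overlap`` genes).  Results sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query genes must be a subset of the universe")
    results = []
    for name in sorted(sets):
        members = set(sets[name]) & uni
        overlap = q & members
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(M=|universe|, K=|set|, n=|query|)
        p = float(hypergeom.sf(k - 1, len(uni), len(members), len(q)))
        p = min(max(p, 0.0), 1.0)
        results.append(EnrichmentResult(
            set_name=name, overlap_count=k, overlap_genes=frozenset(overlap),
            p_value=p, significant=bool(p < p_cutoff and k > min_overlap),
            set_size=len(members),
        ))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
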