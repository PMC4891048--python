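"""Synthetic cell-line panel generator with planted ground truth.

Generates a small panel shaped like the large public pharmacogenomic
screens (a drug x cell-line pIC50 matrix with missing entries, log2
expression, gene-level copy number, mutation calls, binary drug
fingerprints and cancer-type annotation) in which every pipeline stage has
a recoverable planted answer:

* the response matrix is a nonnegative rank-``k_true`` product U V^T plus
  Gaussian noise, with V linearly driven by a row-sparse set of driver
  genes per cancer type (the group-lasso target);
* CNV tracks expression for a configurable fraction of genes and is
  independent noise for the rest;
* a few cell lines are planted as genomic outliers (aberrant CNV shift and
  a burst of nonsilent mutations);
* per drug, a disjoint set of resistance genes is planted whose expression
  AND copy number are monotone in that drug's pIC50 with concordant signs;
* fingerprints have family block structure so Tanimoto similarity is
  informative.

Everything is reproducible bit-for-bit from the single ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (
    FingerprintMatrix,
    MutationTable,
    OmicsMatrix,
    Panel,
    PanelAnnotation,
    ResponseMatrix,
)

__all__ = ["SyntheticTruth", "simulate_panel", "simulate_signature_sets"]


@dataclass
class SyntheticTruth:
    U_true: np.ndarray
    V_true: np.ndarray
    Q_true: dict[str, np.ndarray]  # cancer type -> genes x k row-sparse loading
    Q_support: dict[str, frozenset[str]]
    resistance_genes: dict[str, dict[str, int]]  # drug -> gene -> planted sign
    outlier_ids: frozenset[str]
    noise_sd: float
    seed: int
    params: dict = field(default_factory=dict)


def simulate_signature_sets(totals: dict[str, int], uniques: dict[str, int]):
    """Build signature sets with prescribed sizes and type-unique counts.

    For each type, ``uniques[t]`` private genes are created; the remaining
    ``totals[t] - uniques[t]`` memberships are filled with genes shared
    between exactly two types (largest remaining demands paired first).
    Useful for reproducing published overlap statistics, where the per-type
    totals and unique counts are the known inputs.
    """
    from .grouplasso import SignatureSet

    names = list(totals)
    if set(uniques) != set(names):
        raise ValueError("totals and uniques must cover the same types")
    shared_demand = {}
    for t in names:
        d = totals[t] - uniques[t]
        if d < 0:
            raise ValueError(f"unique count exceeds total for {t!r}")
        shared_demand[t] = d
    if sum(shared_demand.values()) % 2:
        raise ValueError("shared memberships must pair up; demands have odd sum")
    members: dict[str, set[str]] = {t: set() for t in names}
    for t in names:
        members[t] |= {f"{t}_u{i}" for i in range(uniques[t])}
    g = 0
    while any(shared_demand.values()):
        a, b = sorted(names, key=lambda t: -shared_demand[t])[:2]
        if shared_demand[b] == 0:
            raise ValueError("overlap demands are infeasible (one dominant set)")
        gene = f"shared{g:05d}"
        g += 1
        members[a].add(gene)
        members[b].add(gene)
        shared_demand[a] -= 1
        shared_demand[b] -= 1
    return [SignatureSet(t, frozenset(members[t])) for t in names]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_panel(
    n_drugs: int = 30,
    n_cells: int = 120,
    n_genes: int = 500,
    k_true: int = 4,
    n_types: int = 3,
    driver_count: int = 10,
    resist_count: int = 5,
    outlier_count: int = 4,
    missing_fraction: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    cnv_coupling: float = 0.75,
    n_bits: int = 881,
    resist_drugs: int | None = None,
    plant_noise_sd: float = 0.15,
    outlier_shift: float = 3.0,
) -> tuple[Panel, SyntheticTruth]:
    """Generate a full panel plus its planted truth.

    ``resist_drugs`` limits how many drugs get planted resistance genes
    (default: as many as the non-driver gene pool allows).  All counts are
    validated before any generation happens.
    """
    if min(n_drugs, n_cells, n_genes, k_true, n_types) < 1:
        raise ValueError("all counts must be positive")
    if driver_count * n_types > n_genes:
        raise ValueError("driver_count * n_types exceeds n_genes")
    if n_types > n_cells:
        raise ValueError("more cancer types than cell lines")
    if outlier_count >= n_cells:
        raise ValueError("outlier_count must be below n_cells")
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    if not 0.0 <= cnv_coupling <= 1.0:
        raise ValueError("cnv_coupling must be in [0, 1]")
    n_free = n_genes - driver_count * n_types
    if resist_drugs is None:
        resist_drugs = min(n_drugs, n_free // resist_count if resist_count else 0)
    if resist_count * resist_drugs > n_free:
        raise ValueError("not enough non-driver genes for the requested resistance planting")

    streams = np.random.SeedSequence(seed).spawn(8)
    rng_expr, rng_fac, rng_resp, rng_cnv, rng_mut, rng_fp, rng_res, rng_out = (
        np.random.default_rng(s) for s in streams
    )

    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    cells = [f"CL{i:04d}" for i in range(n_cells)]
    genes = [f"G{i:05d}" for i in range(n_genes)]
    types = [f"type{t + 1}" for t in range(n_types)]
    type_of = {c: types[i % n_types] for i, c in enumerate(cells)}
    annotation = PanelAnnotation(cancer_type=dict(type_of))

    # (1) expression: log2-array-like marginals with cancer-type block shifts
    expr = rng_expr.normal(7.0, 2.0, size=(n_genes, n_cells))
    block = max(1, n_genes // 10)
    for t, tname in enumerate(types):
        shifted = rng_expr.choice(n_genes, size=block, replace=False)
        cols = [i for i, c in enumerate(cells) if type_of[c] == tname]
        expr[np.ix_(shifted, cols)] += rng_expr.normal(2.0, 0.5)

    # (2) V driven by a planted row-sparse signed loading per cancer type,
    # around a positive baseline so V stays nonnegative: within each type,
    # V = v_base + (E - mean)^T Q with Q zero outside the driver rows
    v_base = 1.0
    v_amp = 0.25  # ~4 sd below v_base, so the nonnegativity clip is inactive
    perm = rng_fac.permutation(n_genes)
    v = np.zeros((n_cells, k_true))
    q_true: dict[str, np.ndarray] = {}
    q_support: dict[str, frozenset[str]] = {}
    for t, tname in enumerate(types):
        drv = np.sort(perm[t * driver_count:(t + 1) * driver_count])
        q = np.zeros((n_genes, k_true))
        q[drv] = (rng_fac.uniform(0.5, 1.5, size=(driver_count, k_true))
                  * rng_fac.choice((-1.0, 1.0), size=(driver_count, k_true)))
        cols = [i for i, c in enumerate(cells) if type_of[c] == tname]
        e_c = expr[:, cols] - expr[:, cols].mean(axis=1, keepdims=True)
        raw = e_c.T @ q
        sd = raw.std() if raw.std() > 0 else 1.0
        q *= v_amp / sd
        v[cols] = v_base + raw * (v_amp / sd)
        q_true[tname] = q
        q_support[tname] = frozenset(genes[i] for i in drv)
    v = np.maximum(v, 0.0)

    # (3) nonnegative drug factors scaled so S sits in a pIC50-like range
    u = rng_fac.uniform(0.5, 1.0, size=(n_drugs, k_true)) * (6.0 / (0.75 * k_true))

    # (4) response with noise and a missing mask (never a fully-missing axis)
    s = u @ v.T
    if noise_sd > 0:
        s = s + rng_resp.normal(0.0, noise_sd, size=s.shape)
    observed = rng_resp.uniform(size=s.shape) >= missing_fraction
    for d in range(n_drugs):
        observed[d, d % n_cells] = True
    for c in range(n_cells):
        observed[c % n_drugs, c] = True
    response = ResponseMatrix(drugs, cells, np.where(observed, s, 0.0), observed)

    # (5) CNV: coupled to expression for a fraction of genes, noise otherwise
    coupled = rng_cnv.uniform(size=n_genes) < cnv_coupling
    cnv = rng_cnv.normal(0.0, 0.3, size=(n_genes, n_cells))
    cnv[coupled] = 0.25 * (expr[coupled] - 7.0) + rng_cnv.normal(
        0.0, 0.1, size=(int(coupled.sum()), n_cells))

    # (7) planted per-drug resistance genes: expression and CNV monotone in
    # pIC50 with concordant signs (planted before outlier aberration so the
    # outlier stage genuinely disturbs them)
    free = [i for i in perm[driver_count * n_types:]]
    resistance: dict[str, dict[str, int]] = {}
    pos = 0
    for d in range(resist_drugs):
        picked = free[pos:pos + resist_count]
        pos += resist_count
        y = _zscore(s[d])
        signs = {}
        for gi in picked:
            sign = int(rng_res.choice((-1, 1)))
            expr[gi] = 7.0 + sign * 1.5 * y + rng_res.normal(0.0, plant_noise_sd, n_cells)
            cnv[gi] = sign * 0.8 * y + rng_res.normal(0.0, plant_noise_sd / 2.0, n_cells)
            signs[genes[gi]] = sign
        resistance[drugs[d]] = signs

    # (6) outlier cell lines: aberrant CNV shift plus a nonsilent burst
    out_idx = rng_out.choice(n_cells, size=outlier_count, replace=False) if outlier_count else []
    outlier_ids = frozenset(cells[i] for i in out_idx)
    for i in out_idx:
        hit = rng_out.choice(n_genes, size=max(1, n_genes // 3), replace=False)
        cnv[hit, i] += outlier_shift * rng_out.choice((-1.0, 1.0), size=hit.size)

    # mutation calls: sparse background, silent and nonsilent, burst in outliers
    records = []
    for ci, c in enumerate(cells):
        n_ns = rng_mut.poisson(5) + (40 if c in outlier_ids else 0)
        n_si = rng_mut.poisson(5)
        for gi in rng_mut.choice(n_genes, size=min(n_ns, n_genes), replace=False):
            records.append((genes[gi], c, "nonsilent"))
        for gi in rng_mut.choice(n_genes, size=min(n_si, n_genes), replace=False):
            records.append((genes[gi], c, "silent"))
    mut = MutationTable(
        pd.DataFrame(records, columns=["gene", "cell_line", "effect_class"])
        .drop_duplicates()
    )

    # (8) fingerprints with family block structure
    n_fam = max(2, min(4, n_drugs))
    fam_of = np.arange(n_drugs) % n_fam
    base = (rng_fp.uniform(size=(n_fam, n_bits)) < 0.3).astype(np.int8)
    bits = base[fam_of].copy()
    flip = rng_fp.uniform(size=bits.shape) < 0.05
    bits = np.where(flip, 1 - bits, bits)
    for d in range(n_drugs):  # no all-zero fingerprints
        if bits[d].sum() == 0:
            bits[d, d % n_bits] = 1
    fingerprints = FingerprintMatrix(drugs, bits)

    panel = Panel(
        expression=OmicsMatrix("expression", genes, cells, expr),
        cnv=OmicsMatrix("cnv", genes, cells, cnv),
        mutations=mut,
        response=response,
        fingerprints=fingerprints,
        annotation=annotation,
    )
    truth = SyntheticTruth(
        U_true=u, V_true=v, Q_true=q_true, Q_support=q_support,
        resistance_genes=resistance, outlier_ids=outlier_ids,
        noise_sd=noise_sd, seed=seed,
        params={
            "n_drugs": n_drugs, "n_cells": n_cells, "n_genes": n_genes,
            "k_true": k_true, "n_types": n_types, "driver_count": driver_count,
            "resist_count": resist_count, "outlier_count": outlier_count,
            "missing_fraction": missing_fraction, "cnv_coupling": cnv_coupling,
            "n_bits": n_bits, "v_base": v_base, "v_amp": v_amp,
        },
    )
    return panel, truth
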