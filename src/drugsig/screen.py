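"""Primary-resistance gene screen.

For one drug on one cancer type, candidate resistance genes are screened in
four stages: (1) cell lines whose CNV or (nonsilent) mutation profile lies
far from the panel's geometric center are excluded as outliers, so the
remaining lines share a concordant genomic background; (2) the drug's pIC50
values over the remaining lines are discretized into sensitive (+1),
moderate (0) and resistant (-1) calls; (3) over the sensitive and resistant
lines only, each candidate gene's expression and CNV are correlated
(Spearman) with the drug activity; (4) a gene passes when both correlations
are strong (|rho| above the cutoff, default 0.7) and sign-concordant with
each other — expression and copy number must move the same way with drug
activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .grouplasso import SignatureSet
from .panel import MutationTable, OmicsMatrix, Panel, PanelAnnotation, ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityCall",
    "ScreenHit",
    "ScreenConfig",
    "detect_outliers",
    "exclude_silent",
    "discretize_activity",
    "spearman_screen",
    "run_resistance_screen",
]


@dataclass
class ActivityCall:
    """Per-drug discretization of cell lines into +1 / 0 / -1."""

    drug: str
    labels: dict[str, int]  # cell line -> {+1, 0, -1}
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.labels.values()) - {-1, 0, 1}
        if bad:
            raise ValueError(f"labels must be in {{+1,0,-1}}, got {sorted(bad)}")

    def lines_with(self, label: int) -> list[str]:
        return sorted(c for c, v in self.labels.items() if v == label)

    @property
    def informative_lines(self) -> list[str]:
        return sorted(c for c, v in self.labels.items() if v != 0)


@dataclass
class ScreenHit:
    drug: str
    gene: str
    rho_expr: float
    rho_cnv: float
    passed: bool
    reason: str = ""


@dataclass(frozen=True)
class ScreenConfig:
    expr_cutoff: float = 0.7
    cnv_cutoff: float = 0.7
    outlier_fraction: float = 0.10
    disc_method: str = "quantile"  # "quantile" | "zscore"
    disc_q: float = 0.25
    zscore_cut: float = 1.0


def detect_outliers(profile: OmicsMatrix, fraction: float = 0.10) -> list[str]:
    """Cell lines furthest (Euclidean) from the panel's componentwise mean.

    Returns the ceil(fraction * n) most distant cell lines; exact distance
    ties are broken lexicographically by cell-line id, so the result is
    deterministic.
    """
    n = len(profile.cell_line_ids)
    if n < 2:
        raise ValueError("need at least two cell lines")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_out = math.ceil(fraction * n)
    if n_out >= n:
        raise ValueError(f"fraction {fraction} would remove all {n} cell lines")
    pts = profile.values.T  # cells x genes
    center = pts.mean(axis=0)
    dist = np.linalg.norm(pts - center, axis=1)
    order = sorted(range(n), key=lambda i: (-dist[i], profile.cell_line_ids[i]))
    return [profile.cell_line_ids[i] for i in order[:n_out]]


def exclude_silent(m: MutationTable) -> MutationTable:
    """Drop silent mutation records, keeping only nonsilent calls."""
    return m.nonsilent()


def discretize_activity(
    responses: pd.Series | dict,
    method: str = "quantile",
    *,
    q: float = 0.25,
    zscore_cut: float = 1.0,
    drug: str = "drug",
) -> ActivityCall:
    """Discretize one drug's per-cell-line pIC50 into {+1, 0, -1} calls.

    Cell lines are sorted by ascending pIC50 (value ties broken by id for
    determinism).  With the "quantile" method the lowest floor(q*n) lines are
    called resistant (-1, low pIC50 = high IC50), the highest floor(q*n)
    sensitive (+1), the middle moderate (0).  With "zscore", lines beyond
    +/- zscore_cut standardized units get +1/-1.  A constant vector yields
    all-moderate calls with a warning.
    """
    s = pd.Series(responses, dtype=float).dropna()
    if len(s) < 4:
        raise ValueError("need at least 4 observed responses to discretize")
    ids = sorted(s.index, key=lambda c: (s[c], str(c)))
    vals = s[ids].to_numpy()
    labels = {c: 0 for c in ids}
    if np.ptp(vals) == 0:
        logger.warning("discretize_activity(%s): constant responses, all moderate", drug)
        return ActivityCall(drug, labels, {"method": method, "degenerate": True})
    if method == "quantile":
        if not 0.0 < q <= 0.5:
            raise ValueError("tail quantile must be in (0, 0.5]")
        t = int(math.floor(q * len(ids)))
        for c in ids[:t]:
            labels[c] = -1
        for c in ids[len(ids) - t:]:
            labels[c] = 1
        params = {"method": "quantile", "q": q, "tail_count": t}
    elif method == "zscore":
        z = (vals - vals.mean()) / vals.std()
        for c, zi in zip(ids, z):
            labels[c] = 1 if zi > zscore_cut else (-1 if zi < -zscore_cut else 0)
        params = {"method": "zscore", "cut": zscore_cut}
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    return ActivityCall(drug, labels, params)


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = spearmanr(x, y).statistic
    return float(rho)


def spearman_screen(
    expr: OmicsMatrix,
    cnv: OmicsMatrix,
    calls: ActivityCall,
    responses: pd.Series | dict,
    candidate_genes: Iterable[str],
    expr_cutoff: float = 0.7,
    cnv_cutoff: float = 0.7,
) -> list[ScreenHit]:
    """Correlate candidate genes with drug activity over the +1/-1 lines.

    A gene passes when |rho_expr| > expr_cutoff, |rho_cnv| > cnv_cutoff and
    the two correlations share a sign.  Zero-variance genes are reported as
    failed with a reason rather than dropped.
    """
    resp = pd.Series(responses, dtype=float)
    lines = [c for c in calls.informative_lines
             if c in expr.cell_line_ids and c in cnv.cell_line_ids and c in resp.index]
    if len(lines) < 4:
        raise ValueError(f"only {len(lines)} sensitive+resistant lines retained; need >= 4")
    if not calls.lines_with(1) or not calls.lines_with(-1):
        raise ValueError("need at least one sensitive and one resistant line")
    e = expr.to_frame()[lines]
    c = cnv.to_frame()[lines]
    y = resp[lines].to_numpy()
    hits: list[ScreenHit] = []
    for gene in sorted(set(candidate_genes)):
        if gene not in e.index or gene not in c.index:
            hits.append(ScreenHit(calls.drug, gene, float("nan"), float("nan"),
                                  False, "gene absent from expression or CNV matrix"))
            continue
        rho_e = _safe_spearman(e.loc[gene].to_numpy(), y)
        rho_c = _safe_spearman(c.loc[gene].to_numpy(), y)
        if math.isnan(rho_e) or math.isnan(rho_c):
            hits.append(ScreenHit(calls.drug, gene, rho_e, rho_c, False,
                                  "zero-variance profile"))
            continue
        ok = (abs(rho_e) > expr_cutoff and abs(rho_c) > cnv_cutoff
              and np.sign(rho_e) == np.sign(rho_c) and rho_e != 0)
        hits.append(ScreenHit(calls.drug, gene, rho_e, rho_c, bool(ok),
                              "" if ok else "below cutoff or sign-discordant"))
    return hits


def run_resistance_screen(
    panel: Panel,
    signatures: SignatureSet,
    drug: str,
    config: ScreenConfig = ScreenConfig(),
) -> list[ScreenHit]:
    """Full screen for one drug on the cell lines of the signature's cancer type.

    Stages: silent-mutation exclusion -> CNV and mutation outlier detection
    (union removed) -> activity discretization -> Spearman screen restricted
    to the signature genes.  Deterministic given the config.
    """
    ann: PanelAnnotation = panel.annotation
    cells = ann.cells_of_type(signatures.cancer_type) if ann.cancer_type else \
        list(panel.expression.cell_line_ids)
    cells = [c for c in cells if c in panel.expression.cell_line_ids
             and c in panel.cnv.cell_line_ids and c in panel.response.cell_line_ids]
    if len(cells) < 4:
        raise ValueError(
            f"outlier stage: cancer type {signatures.cancer_type!r} has too few cell lines")

    outliers: set[str] = set()
    if config.outlier_fraction > 0:
        cnv_sub = panel.cnv.restrict_cells(cells)
        outliers |= set(detect_outliers(cnv_sub, config.outlier_fraction))
        nonsilent = exclude_silent(panel.mutations)
        if len(nonsilent) == 0:
            logger.warning("run_resistance_screen(%s): no nonsilent mutations; "
                           "skipping mutation outlier stage", drug)
        else:
            mut_mat = nonsilent.binary_matrix(cells)
            outliers |= set(detect_outliers(mut_mat, config.outlier_fraction))
    kept = [c for c in cells if c not in outliers]

    resp = panel.response.row(drug)[kept].dropna()
    calls = discretize_activity(resp, config.disc_method, q=config.disc_q,
                                zscore_cut=config.zscore_cut, drug=drug)
    return spearman_screen(
        panel.expression, panel.cnv, calls, resp, signatures.genes,
        expr_cutoff=config.expr_cutoff, cnv_cutoff=config.cnv_cutoff,
    )


def hits_to_frame(hits: Sequence[ScreenHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"drug": h.drug, "gene": h.gene, "rho_expr": h.rho_expr,
          "rho_cnv": h.rho_cnv, "passed": h.passed, "reason": h.reason}
         for h in hits]
    )
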