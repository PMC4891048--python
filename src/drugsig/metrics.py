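"""Scoring metrics for drug-sensitivity predictions.

RMSE for value accuracy; the concordance index (c-index) for ranking
accuracy; a probabilistic c-index (pc-index) that down-weights pairs whose
observed difference is small relative to measurement noise; and the
weighted probabilistic concordance index (wpc-index), a drug-weighted
average of per-drug pc-indices, as used for ranking-challenge style
evaluation across a drug panel.

For a pair (i, j) with observed values o_i != o_j and noise standard
deviation sigma, the pc-index credits Phi(|o_i - o_j| / (sqrt(2) sigma))
when the predicted ordering matches the observed one and the complement
when it does not; at sigma = 0 it reduces to the c-index.  Tied observed
pairs, and tied predictions, contribute 0.5 (Harrell convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

__all__ = ["rmse", "c_index", "probabilistic_c_index", "wpc_index", "RankingEvaluation"]


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error between two equal-length value lists."""
    p = _as_1d(predicted, "predicted")
    o = _as_1d(observed, "observed")
    if p.size != o.size or p.size == 0:
        raise ValueError("predicted and observed must have equal nonzero length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _pairwise_scores(
    predicted: np.ndarray, observed: np.ndarray, noise_sd: float
) -> float:
    n = predicted.size
    iu, ju = np.triu_indices(n, k=1)
    dp = predicted[iu] - predicted[ju]
    do = observed[iu] - observed[ju]
    if noise_sd == 0.0:
        credit = np.where(do == 0, 0.5, np.where(dp == 0, 0.5,
                          (np.sign(dp) == np.sign(do)).astype(float)))
    else:
        phi = norm.cdf(np.abs(do) / (np.sqrt(2.0) * noise_sd))
        concordant = np.sign(dp) == np.sign(do)
        credit = np.where(do == 0, 0.5, np.where(dp == 0, 0.5,
                          np.where(concordant, phi, 1.0 - phi)))
    return float(credit.mean())


def c_index(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Fraction of item pairs ranked concordantly; ties credit 0.5.

    ``predicted`` may be predicted values or predicted ranks — only the
    ordering matters.
    """
    p = _as_1d(predicted, "predicted")
    o = _as_1d(observed, "observed")
    if p.size != o.size:
        raise ValueError("length mismatch")
    if p.size < 2:
        raise ValueError("need at least two items")
    return _pairwise_scores(p, o, 0.0)


def probabilistic_c_index(
    predicted: Sequence[float], observed: Sequence[float], noise_sd: float
) -> float:
    """Noise-weighted concordance: pairs barely separated in the observed
    values (relative to ``noise_sd``) count close to 0.5 either way."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    p = _as_1d(predicted, "predicted")
    o = _as_1d(observed, "observed")
    if p.size != o.size:
        raise ValueError("length mismatch")
    if p.size < 2:
        raise ValueError("need at least two items")
    return _pairwise_scores(p, o, noise_sd)


@dataclass
class RankingEvaluation:
    """Per-drug pc-indices, their weights, and the weighted average."""

    per_drug_pc: dict[str, float]
    drug_weights: dict[str, float]
    wpc: float


def wpc_index(
    per_drug_scores: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> RankingEvaluation:
    """Weighted average of per-drug pc-indices (uniform weights by default)."""
    if not per_drug_scores:
        raise ValueError("no per-drug scores")
    drugs = list(per_drug_scores)
    if weights is None:
        weights = {d: 1.0 for d in drugs}
    if set(weights) != set(drugs):
        raise ValueError("weights must cover exactly the scored drugs")
    w = np.array([weights[d] for d in drugs], dtype=float)
    s = np.array([per_drug_scores[d] for d in drugs], dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    return RankingEvaluation(
        per_drug_pc=dict(zip(drugs, s)),
        drug_weights=dict(zip(drugs, w)),
        wpc=float(np.dot(w, s) / w.sum()),
    )
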