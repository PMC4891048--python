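"""Signature-gene selection by sparse group lasso.

The fitted cell-line factors V (cells x k) are regressed onto gene
expression features F^C (cells x h2), and the drug factors U onto structural
fingerprint features F^D, via the row-grouped sparse regression

    min_W  || Y - X W ||_F^2  +  lambda_group * sum_j ||W_j.||_2
                              +  lambda_l1 * ||W||_1,

where each group is the full coefficient row of one feature across all k
latent dimensions.  A feature whose row survives with nonzero l2 norm is
"selected"; for gene features restricted to the cell lines of one cancer
type, the selected genes are that type's drug-response signature genes.

The solver is proximal block-coordinate descent over rows.  For row j with
column norm a_j = ||x_j||^2 and partial residual correlation c_j, the exact
row update is the sparse-group-lasso proximal operator

    s   = soft(c_j / a_j, lambda_l1 / (2 a_j))
    W_j = 0                                if ||s||_2 <= lambda_group / (2 a_j)
        = (1 - lambda_group / (2 a_j ||s||_2)) * s   otherwise,

from which the exact all-kill threshold follows: with W = 0 optimal, every
row j must satisfy ||soft(2 x_j^T Y, lambda_l1)||_2 <= lambda_group, i.e.
for lambda_l1 = 0 a penalty of 2 * max_j ||x_j^T Y||_2 zeroes everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import FingerprintMatrix, OmicsMatrix

__all__ = [
    "FeatureWeightMatrix",
    "SignatureSet",
    "fit_group_sparse_lasso",
    "group_kill_threshold",
    "kkt_violation",
    "select_signatures",
    "signature_overlap_stats",
]

ZERO_TOL = 1e-8


@dataclass
class FeatureWeightMatrix:
    """Row-sparse weight matrix from the group-lasso fit.

    ``role`` records which side was fit: "gene_features" (Q: h2 x k) or
    "drug_features" (P: h1 x k).
    """

    role: str
    feature_ids: list[str]
    weights: np.ndarray  # features x k
    zero_tol: float = ZERO_TOL
    lambda_group: float = 0.0
    lambda_l1: float = 0.0
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.role not in ("gene_features", "drug_features"):
            raise ValueError(f"unknown role {self.role!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")
        if self.weights.shape[0] != len(self.feature_ids):
            raise ValueError("weight rows do not match feature ids")

    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.weights, axis=1)

    def selected(self) -> list[str]:
        norms = self.row_norms()
        return [f for f, nz in zip(self.feature_ids, norms > self.zero_tol) if nz]


@dataclass
class SignatureSet:
    """Signature genes for one cancer type, with fitting provenance."""

    cancer_type: str
    genes: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def _objective(
    w: np.ndarray, gram: np.ndarray, xty: np.ndarray, yty: float,
    lambda_group: float, lambda_l1: float,
) -> float:
    fit = yty - 2.0 * float(np.sum(w * xty)) + float(np.sum(w * (gram @ w)))
    pen = lambda_group * float(np.linalg.norm(w, axis=1).sum())
    pen += lambda_l1 * float(np.abs(w).sum())
    return fit + pen


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def fit_group_sparse_lasso(
    targets: np.ndarray,
    features: np.ndarray,
    lambda_group: float,
    lambda_l1: float = 0.0,
    *,
    feature_ids: Sequence[str] | None = None,
    role: str = "gene_features",
    max_iter: int = 500,
    tol: float = 1e-9,
    zero_tol: float = ZERO_TOL,
    w0: np.ndarray | None = None,
) -> FeatureWeightMatrix:
    """Solve the row-grouped sparse regression of ``targets`` on ``features``.

    ``targets`` is n x k (a factor matrix), ``features`` n x h.  Returns the
    h x k weight matrix with its objective trace (non-increasing by
    construction of the exact row prox).
    """
    y = np.asarray(targets, dtype=float)
    x = np.asarray(features, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if lambda_group < 0 or lambda_l1 < 0:
        raise ValueError("penalty weights must be nonnegative")
    if x.shape[0] != y.shape[0]:
        raise ValueError("targets and features must have aligned rows")
    n, h = x.shape
    k = y.shape[1]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(h)]

    gram = x.T @ x
    xty = x.T @ y
    yty = float(np.sum(y ** 2))
    a = np.diag(gram).copy()
    dead = a <= 0  # constant-zero feature columns can never be selected

    w = np.zeros((h, k)) if w0 is None else np.array(w0, dtype=float, copy=True)
    trace = [_objective(w, gram, xty, yty, lambda_group, lambda_l1)]
    converged = False
    for _ in range(max_iter):
        for j in range(h):
            if dead[j]:
                w[j] = 0.0
                continue
            cj = xty[j] - gram[j] @ w + a[j] * w[j]
            z = cj / a[j]
            s = _soft(z, lambda_l1 / (2.0 * a[j])) if lambda_l1 else z
            ns = np.linalg.norm(s)
            thr = lambda_group / (2.0 * a[j])
            if ns <= thr:
                w[j] = 0.0
            else:
                w[j] = (1.0 - thr / ns) * s
        j_now = _objective(w, gram, xty, yty, lambda_group, lambda_l1)
        trace.append(j_now)
        if abs(trace[-2] - j_now) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break

    return FeatureWeightMatrix(
        role=role, feature_ids=list(feature_ids), weights=w, zero_tol=zero_tol,
        lambda_group=lambda_group, lambda_l1=lambda_l1,
        objective_trace=trace, converged=converged,
    )


def group_kill_threshold(targets: np.ndarray, features: np.ndarray,
                         lambda_l1: float = 0.0) -> float:
    """Smallest lambda_group at which the all-zero solution is optimal."""
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(features, dtype=float)
    corr = 2.0 * (x.T @ y)
    if lambda_l1:
        corr = _soft(corr, lambda_l1)
    return float(np.linalg.norm(corr, axis=1).max())


def kkt_violation(fit: FeatureWeightMatrix, targets: np.ndarray,
                  features: np.ndarray) -> float:
    """Maximum KKT violation of a fitted weight matrix (0 at an exact optimum).

    Zero rows must satisfy ||soft(2 x_j^T r, lambda_l1)||_2 <= lambda_group;
    nonzero rows must have a vanishing subgradient.
    """
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(features, dtype=float)
    w = fit.weights
    resid = y - x @ w
    corr = 2.0 * (x.T @ resid)  # negative gradient of the fit term
    worst = 0.0
    norms = fit.row_norms()
    for j in range(w.shape[0]):
        if norms[j] <= fit.zero_tol:
            v = np.linalg.norm(_soft(corr[j], fit.lambda_l1)) - fit.lambda_group
            worst = max(worst, v)
        else:
            sub = corr[j] - fit.lambda_group * w[j] / norms[j]
            nzc = w[j] != 0
            sub = np.where(nzc, sub - fit.lambda_l1 * np.sign(w[j]),
                           np.sign(sub) * np.maximum(np.abs(sub) - fit.lambda_l1, 0.0))
            worst = max(worst, float(np.abs(sub).max()))
    return float(worst)


def lasso_path(
    targets: np.ndarray,
    features: np.ndarray,
    lambdas: Sequence[float],
    lambda_l1: float = 0.0,
    **opts,
) -> list[FeatureWeightMatrix]:
    """Fit along a decreasing lambda_group path with warm starts."""
    order = np.argsort(lambdas)[::-1]
    fits: dict[int, FeatureWeightMatrix] = {}
    w0 = None
    for idx in order:
        fit = fit_group_sparse_lasso(targets, features, float(lambdas[idx]),
                                     lambda_l1, w0=w0, **opts)
        w0 = fit.weights
        fits[int(idx)] = fit
    return [fits[i] for i in range(len(lambdas))]


def select_signatures(
    factors: np.ndarray,
    features: OmicsMatrix | FingerprintMatrix,
    cancer_type: str,
    lambdas: Sequence[float],
    *,
    cell_lines: Sequence[str] | None = None,
    lambda_l1: float = 0.0,
    target_size: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    zero_tol: float = ZERO_TOL,
    standardize: bool = True,
) -> SignatureSet:
    """Select signature genes for one cancer type.

    ``factors`` are the V rows of that type's cell lines (l x k); ``features``
    the expression matrix restricted to the same cell lines in the same
    order (or, for drug-structure selection, a fingerprint matrix whose rows
    align with U).  The group-lasso path over ``lambdas`` is fit and the
    penalty is chosen either by ``target_size`` (support closest to the
    requested size, ties to the larger penalty) or by ``cv_folds``-fold CV
    on reconstruction error.
    """
    if isinstance(features, OmicsMatrix):
        if cell_lines is not None:
            features = features.restrict_cells(cell_lines)
        x = features.values.T  # cells x genes
        ids = list(features.gene_ids)
        role = "gene_features"
    else:
        x = features.bits.astype(float)
        ids = list(features.drug_ids)
        role = "drug_features"
    y = np.asarray(factors, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("factor rows and feature rows are not aligned")
    if role == "gene_features" and y.shape[0] < 3:
        raise ValueError(f"cancer type {cancer_type!r} has fewer than 3 cell lines")
    if standardize:
        # center y as well: the model has no intercept, and support recovery
        # is unaffected by a constant shift of the targets
        mu, sd = x.mean(axis=0), x.std(axis=0)
        x = (x - mu) / np.where(sd > 0, sd, 1.0)
        y = y - y.mean(axis=0)

    lambdas = sorted(float(l) for l in lambdas)
    if target_size is not None:
        fits = lasso_path(y, x, lambdas, lambda_l1, feature_ids=ids,
                          role=role, zero_tol=zero_tol)
        sizes = [len(f.selected()) for f in fits]
        # ties broken toward the larger penalty (sparser model)
        best = max(range(len(lambdas)), key=lambda i: (-abs(sizes[i] - target_size), i))
        chosen, fit = lambdas[best], fits[best]
    else:
        rng = np.random.default_rng(seed)
        fold_of = rng.permutation(np.arange(y.shape[0]) % cv_folds)
        errs = np.zeros(len(lambdas))
        for f in range(cv_folds):
            tr, te = fold_of != f, fold_of == f
            if te.sum() == 0:
                continue
            fits = lasso_path(y[tr], x[tr], lambdas, lambda_l1,
                              feature_ids=ids, role=role, zero_tol=zero_tol)
            for i, ft in enumerate(fits):
                errs[i] += float(np.sum((y[te] - x[te] @ ft.weights) ** 2))
        best = int(np.argmin(errs))
        chosen = lambdas[best]
        fit = fit_group_sparse_lasso(y, x, chosen, lambda_l1, feature_ids=ids,
                                     role=role, zero_tol=zero_tol)

    genes = frozenset(fit.selected())
    return SignatureSet(
        cancer_type=cancer_type,
        genes=genes,
        provenance={
            "lambda_group": chosen,
            "lambda_l1": lambda_l1,
            "k": int(y.shape[1]),
            "n_cell_lines": int(y.shape[0]),
            "seed": seed,
            "support_size": len(genes),
            "empty": len(genes) == 0,
        },
    )


def signature_overlap_stats(sets: Sequence[SignatureSet]) -> dict:
    """Totals, type-unique counts/percentages, and pairwise overlaps.

    For each signature set: total gene count, the number of genes appearing
    in no other set, and the unique percentage 100*unique/total rounded to
    two decimals (None for an empty set).  Also returns the full pairwise
    intersection-count matrix.
    """
    if len(sets) < 2:
        raise ValueError("need at least two signature sets")
    per_type: dict[str, dict] = {}
    for i, s in enumerate(sets):
        others: set[str] = set()
        for j, o in enumerate(sets):
            if j != i:
                others |= set(o.genes)
        unique = set(s.genes) - others
        total = len(s.genes)
        per_type[s.cancer_type] = {
            "total": total,
            "unique": len(unique),
            "unique_pct": round(100.0 * len(unique) / total, 2) if total else None,
        }
    names = [s.cancer_type for s in sets]
    overlap = {
        a.cancer_type: {b.cancer_type: len(set(a.genes) & set(b.genes)) for b in sets}
        for a in sets
    }
    return {"per_type": per_type, "pairwise": overlap, "order": names}
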