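"""Collaborative-filtering drug-sensitivity model.

The response matrix S (drugs x cell lines, pIC50, partially observed) is
approximated by a nonnegative low-rank product U V^T.  Structure is shared
across drugs and cell lines through two similarity graphs: the drug rows of
U are pulled together according to fingerprint Tanimoto similarity W^D, and
the cell-line rows of V according to expression cosine similarity W^C.  The
fitted objective is

    J(U, V) = || M o (S - U V^T) ||_F^2
              + alpha_drug * tr(U^T L_D U) + alpha_cell * tr(V^T L_C V)
              + gamma * (||U||_F^2 + ||V||_F^2),      U, V >= 0,

with M the observed mask and L_D, L_C unnormalized graph Laplacians of the
(nonnegatively clipped, zero-diagonal) similarity matrices.  Optimization is
by multiplicative updates, which preserve nonnegativity and do not increase
J; a projected-gradient solver is available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ResponseMatrix
from .similarity import SimilarityMatrix

__all__ = ["CFHyperparameters", "FactorModel", "fit_cf", "predict", "cross_validate"]

_EPS = 1e-12


@dataclass(frozen=True)
class CFHyperparameters:
    k: int = 10
    alpha_drug: float = 0.1
    alpha_cell: float = 0.1
    gamma: float = 0.01
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("rank k must be >= 1")
        if min(self.alpha_drug, self.alpha_cell, self.gamma) < 0:
            raise ValueError("regularization weights must be nonnegative")


@dataclass
class FactorModel:
    U: np.ndarray  # drugs x k, nonnegative
    V: np.ndarray  # cells x k, nonnegative
    hyper: CFHyperparameters
    drug_ids: list[str] = field(default_factory=list)
    cell_line_ids: list[str] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.U.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.U @ self.V.T


def _laplacian(sim: SimilarityMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency (clipped at 0, zero diagonal) and its degree matrix."""
    w = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    w = np.clip(w, 0.0, None)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w, np.diag(w.sum(axis=1))


def _objective(
    s: np.ndarray, m: np.ndarray, u: np.ndarray, v: np.ndarray,
    wd: np.ndarray, dd: np.ndarray, wc: np.ndarray, dc: np.ndarray,
    alpha_drug: float, alpha_cell: float, gamma: float,
) -> float:
    resid = m * (s - u @ v.T)
    j = float(np.sum(resid ** 2))
    if alpha_drug:
        j += alpha_drug * float(np.sum(u * ((dd - wd) @ u)))
    if alpha_cell:
        j += alpha_cell * float(np.sum(v * ((dc - wc) @ v)))
    if gamma:
        j += gamma * (float(np.sum(u ** 2)) + float(np.sum(v ** 2)))
    return j


def fit_cf(
    s: ResponseMatrix,
    wd: SimilarityMatrix | None,
    wc: SimilarityMatrix | None,
    hyper: CFHyperparameters | None = None,
    *,
    solver: str = "mu",
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FactorModel:
    """Fit the similarity-regularized masked nonnegative factorization.

    Requires every drug and every cell line to have at least one observed
    response.  Returns a model whose objective trace is non-increasing and
    which stopped on relative tolerance or the iteration cap.
    """
    hyper = hyper or CFHyperparameters()
    mat = np.asarray(s.values, dtype=float)
    mask = np.asarray(s.observed, dtype=float)
    n_d, n_c = mat.shape
    if (mask.sum(axis=1) == 0).any():
        bad = s.drug_ids[int(np.argmin(mask.sum(axis=1)))]
        raise ValueError(f"drug {bad!r} has no observed responses")
    if (mask.sum(axis=0) == 0).any():
        bad = s.cell_line_ids[int(np.argmin(mask.sum(axis=0)))]
        raise ValueError(f"cell line {bad!r} has no observed responses")

    if wd is not None and list(wd.ids) != list(s.drug_ids):
        raise ValueError("drug similarity matrix is not aligned with the response matrix")
    if wc is not None and list(wc.ids) != list(s.cell_line_ids):
        raise ValueError("cell similarity matrix is not aligned with the response matrix")

    w_d, d_d = _laplacian(wd) if wd is not None else (np.zeros((n_d, n_d)),) * 2
    w_c, d_c = _laplacian(wc) if wc is not None else (np.zeros((n_c, n_c)),) * 2

    if init is not None:
        u = np.array(init[0], dtype=float, copy=True)
        v = np.array(init[1], dtype=float, copy=True)
        if u.shape != (n_d, hyper.k) or v.shape != (n_c, hyper.k):
            raise ValueError("init shapes do not match problem dimensions")
        if u.min() < 0 or v.min() < 0:
            raise ValueError("init factors must be nonnegative")
    else:
        rng = np.random.default_rng(hyper.seed)
        scale = max(mat[mask > 0].mean(), _EPS) / np.sqrt(hyper.k)
        u = rng.uniform(_EPS, scale, size=(n_d, hyper.k))
        v = rng.uniform(_EPS, scale, size=(n_c, hyper.k))

    ms = mask * mat
    args = (w_d, d_d, w_c, d_c, hyper.alpha_drug, hyper.alpha_cell, hyper.gamma)
    trace = [_objective(mat, mask, u, v, *args)]

    if solver == "mu":
        for _ in range(hyper.max_iter):
            num = ms @ v + hyper.alpha_drug * (w_d @ u)
            den = (mask * (u @ v.T)) @ v + hyper.alpha_drug * (d_d @ u) + hyper.gamma * u
            u = u * (num / np.maximum(den, _EPS))
            num = ms.T @ u + hyper.alpha_cell * (w_c @ v)
            den = (mask * (u @ v.T)).T @ u + hyper.alpha_cell * (d_c @ v) + hyper.gamma * v
            v = v * (num / np.maximum(den, _EPS))
            j = _objective(mat, mask, u, v, *args)
            if not np.isfinite(j):
                raise ArithmeticError(f"objective diverged at iteration {len(trace)}")
            trace.append(j)
            if abs(trace[-2] - j) <= hyper.tol * max(abs(trace[-2]), _EPS):
                break
    elif solver == "pgd":
        step = 1.0 / (4.0 * max(np.linalg.norm(ms), 1.0))
        for _ in range(hyper.max_iter):
            resid = mask * (u @ v.T - mat)
            gu = 2.0 * (resid @ v + hyper.alpha_drug * ((d_d - w_d) @ u) + hyper.gamma * u)
            gv = 2.0 * (resid.T @ u + hyper.alpha_cell * ((d_c - w_c) @ v) + hyper.gamma * v)
            # backtracking line search keeps the trace monotone
            t = step
            for _ls in range(40):
                u2 = np.maximum(u - t * gu, 0.0)
                v2 = np.maximum(v - t * gv, 0.0)
                j = _objective(mat, mask, u2, v2, *args)
                if j <= trace[-1]:
                    break
                t /= 2.0
            u, v = u2, v2
            if not np.isfinite(j):
                raise ArithmeticError(f"objective diverged at iteration {len(trace)}")
            trace.append(j)
            if abs(trace[-2] - j) <= hyper.tol * max(abs(trace[-2]), _EPS):
                break
    else:
        raise ValueError(f"unknown solver {solver!r}")

    return FactorModel(
        U=u, V=v, hyper=hyper,
        drug_ids=list(s.drug_ids), cell_line_ids=list(s.cell_line_ids),
        objective_trace=trace,
    )


def predict(
    model: FactorModel,
    drug_idx: Sequence[int] | np.ndarray,
    cell_idx: Sequence[int] | np.ndarray,
) -> np.ndarray:
    """Predicted pIC50 at (drug, cell) index pairs; defined for unobserved entries."""
    di = np.asarray(drug_idx, dtype=int)
    ci = np.asarray(cell_idx, dtype=int)
    if di.size and (di.min() < 0 or di.max() >= model.U.shape[0]):
        raise IndexError("drug index out of range")
    if ci.size and (ci.min() < 0 or ci.max() >= model.V.shape[0]):
        raise IndexError("cell index out of range")
    return np.einsum("ik,ik->i", model.U[di], model.V[ci])


def _entry_folds(
    observed: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold label per observed entry, stratified by drug; -1 elsewhere."""
    labels = np.full(observed.shape, -1, dtype=int)
    for d in range(observed.shape[0]):
        cols = np.where(observed[d])[0]
        perm = rng.permutation(cols)
        labels[d, perm] = np.arange(perm.size) % folds
    return labels


def cross_validate(
    s: ResponseMatrix,
    wd: SimilarityMatrix | None,
    wc: SimilarityMatrix | None,
    grid: Sequence[CFHyperparameters],
    folds: int = 5,
    seed: int = 0,
) -> tuple[CFHyperparameters, pd.DataFrame]:
    """Entry-wise cross-validation over a hyperparameter grid.

    Observed entries are split into folds stratified by drug; each grid
    point is fit on the training entries and scored by RMSE on the held-out
    entries.  Returns the grid point with the lowest mean RMSE (first on
    ties) and the full per-fold table.  Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("need at least two folds")
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    rng = np.random.default_rng(seed)
    labels = _entry_folds(s.observed, folds, rng)
    for f in range(folds):
        if not (labels == f).any():
            raise ValueError(f"fold {f} has no held-out entries")
    rows = []
    for gi, hp in enumerate(grid):
        for f in range(folds):
            held = labels == f
            train_obs = s.observed & ~held
            train = ResponseMatrix(
                list(s.drug_ids), list(s.cell_line_ids), s.values, train_obs
            )
            model = fit_cf(train, wd, wc, hp)
            pred = model.reconstruction()[held]
            rmse = float(np.sqrt(np.mean((pred - s.values[held]) ** 2)))
            rows.append({"grid_index": gi, "fold": f, "rmse": rmse})
    table = pd.DataFrame(rows)
    means = table.groupby("grid_index", sort=True)["rmse"].mean()
    best = int(means.idxmin())  # idxmin returns the first minimum -> tie to first
    return grid[best], table
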