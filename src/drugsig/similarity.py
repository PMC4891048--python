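"""Side-information similarity matrices.

Two similarity graphs feed the collaborative-filtering model: cosine
similarity between cell-line expression profiles (W^C) and Tanimoto
similarity between drug fingerprints (W^D).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FingerprintMatrix, OmicsMatrix

__all__ = ["SimilarityMatrix", "cosine_cell_similarity", "tanimoto_drug_similarity"]

_SYM_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str  # "cosine" | "tanimoto"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over ids")
        if self.metric not in ("cosine", "tanimoto"):
            raise ValueError(f"unknown similarity metric {self.metric!r}")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("similarity matrix must have unit diagonal")
        lo = -1.0 if self.metric == "cosine" else 0.0
        if self.values.min() < lo - 1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError(f"{self.metric} similarity out of range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


def cosine_cell_similarity(x: OmicsMatrix, *, center: bool = False) -> SimilarityMatrix:
    """Cosine similarity between cell-line profiles (columns of ``x``).

    ``center=True`` subtracts each profile's mean first, turning cosine into
    Pearson correlation; the default works on raw profiles.
    """
    if len(x.cell_line_ids) < 2:
        raise ValueError("need at least two cell lines")
    v = x.values.T.astype(float)  # cells x genes
    if center:
        v = v - v.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(v, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"zero-norm profile for cell line {x.cell_line_ids[zero[0]]!r}")
    w = (v @ v.T) / np.outer(norms, norms)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return SimilarityMatrix(list(x.cell_line_ids), w, "cosine")


def tanimoto_drug_similarity(f: FingerprintMatrix) -> SimilarityMatrix:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| between fingerprints."""
    if len(f.drug_ids) < 2:
        raise ValueError("need at least two drugs")
    b = f.bits.astype(float)
    counts = b.sum(axis=1)
    zero = np.where(counts == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero fingerprint for drug {f.drug_ids[zero[0]]!r}")
    inter = b @ b.T
    union = counts[:, None] + counts[None, :] - inter
    w = inter / union
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return SimilarityMatrix(list(f.drug_ids), w, "tanimoto")
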