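"""Panel containers and I/O.

Typed containers for the inputs of a pharmacogenomic cell-line panel —
gene-level omics matrices (expression, copy number), per-cell-line mutation
calls, the drug x cell-line response matrix in pIC50 units with an
observed-entry mask, binary structural fingerprints per drug, and panel
annotation (cancer type per cell line, target genes per drug) — plus the
standard preprocessing steps: IC50 -> pIC50 conversion, removal of drugs
with excessive missingness, and alignment of all containers onto a common,
canonically ordered cell-line set.

All tabular I/O is TSV with row ids in the first column and column ids in
the header.  Gene sets are read from standard GMT files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "AlignmentError",
    "OmicsMatrix",
    "MutationTable",
    "ResponseMatrix",
    "FingerprintMatrix",
    "PanelAnnotation",
    "Panel",
    "to_pic50",
    "filter_drugs_by_missingness",
    "align_panels",
    "read_matrix",
    "read_mutations",
    "read_annotation",
    "read_gmt",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class AlignmentError(ValueError):
    """Raised when containers share no common cell lines."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} id(s): {dup[:5]}")
    return ids


@dataclass
class OmicsMatrix:
    """Gene x cell-line real matrix; expression (log2 units) or CNV."""

    kind: str  # "expression" | "cnv"
    gene_ids: list[str]
    cell_line_ids: list[str]
    values: np.ndarray  # genes x cell lines

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "cnv"):
            raise ValueError(f"unknown omics kind {self.kind!r}")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_line_ids = _check_unique(self.cell_line_ids, "cell line")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_line_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"non-finite values in {self.kind} matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_line_ids)

    def restrict_cells(self, cells: Sequence[str]) -> "OmicsMatrix":
        idx = [self.cell_line_ids.index(c) for c in cells]
        return OmicsMatrix(self.kind, list(self.gene_ids), list(cells), self.values[:, idx])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass
class MutationTable:
    """Per-cell-line mutation calls with a silent/nonsilent effect class."""

    records: pd.DataFrame  # columns: gene, cell_line, effect_class

    EFFECTS = ("silent", "nonsilent")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["gene", "cell_line", "effect_class"])
        bad = set(df["effect_class"]) - set(self.EFFECTS)
        if bad:
            raise FormatError(f"unknown mutation effect class(es): {sorted(bad)}")
        if df.duplicated().any():
            raise FormatError("duplicate (gene, cell_line, effect_class) records")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def nonsilent(self) -> "MutationTable":
        return MutationTable(self.records[self.records["effect_class"] == "nonsilent"])

    def binary_matrix(self, cell_line_ids: Sequence[str]) -> OmicsMatrix:
        """Binary gene x cell-line indicator of a (nonsilent) call."""
        genes = sorted(self.records["gene"].unique())
        mat = np.zeros((len(genes), len(cell_line_ids)))
        gpos = {g: i for i, g in enumerate(genes)}
        cpos = {c: i for i, c in enumerate(cell_line_ids)}
        for _, row in self.records.iterrows():
            if row["cell_line"] in cpos:
                mat[gpos[row["gene"]], cpos[row["cell_line"]]] = 1.0
        return OmicsMatrix("cnv", genes, list(cell_line_ids), mat)

    def write(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class ResponseMatrix:
    """Drug x cell-line pIC50 matrix with an observed-entry mask."""

    drug_ids: list[str]
    cell_line_ids: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.cell_line_ids = _check_unique(self.cell_line_ids, "cell line")
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != self.values.shape:
            raise ValueError("mask shape must equal value shape")
        if self.values.shape != (len(self.drug_ids), len(self.cell_line_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise FormatError("non-finite value at an observed entry")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_line_ids)

    def missing_fraction_per_drug(self) -> np.ndarray:
        return 1.0 - self.observed.mean(axis=1)

    def row(self, drug: str) -> pd.Series:
        i = self.drug_ids.index(drug)
        vals = np.where(self.observed[i], self.values[i], np.nan)
        return pd.Series(vals, index=self.cell_line_ids, name=drug)

    def restrict_cells(self, cells: Sequence[str]) -> "ResponseMatrix":
        idx = [self.cell_line_ids.index(c) for c in cells]
        return ResponseMatrix(
            list(self.drug_ids), list(cells), self.values[:, idx], self.observed[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        vals = np.where(self.observed, self.values, np.nan)
        return pd.DataFrame(vals, index=self.drug_ids, columns=self.cell_line_ids)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id", na_rep="")


@dataclass
class FingerprintMatrix:
    """Drug x h1 binary structural fingerprints (881-bit PubChem by default)."""

    drug_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drug_ids):
            raise ValueError("fingerprint shape does not match drug ids")
        if self.bits.shape[1] < 1:
            raise ValueError("fingerprint length must be positive")
        if not np.isin(self.bits, (0, 1)).all():
            raise FormatError("fingerprint entries must be 0/1")
        self.bits = self.bits.astype(np.int8)

    @property
    def h1(self) -> int:
        return self.bits.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bit{i}" for i in range(self.h1)]
        return pd.DataFrame(self.bits, index=self.drug_ids, columns=cols)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass
class PanelAnnotation:
    """Cancer type per cell line and target gene set per drug."""

    cancer_type: dict[str, str] = field(default_factory=dict)
    drug_targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def cells_of_type(self, cancer_type: str) -> list[str]:
        return sorted(c for c, t in self.cancer_type.items() if t == cancer_type)

    @property
    def types(self) -> list[str]:
        return sorted(set(self.cancer_type.values()))

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"cell_line": list(self.cancer_type), "cancer_type": list(self.cancer_type.values())}
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class Panel:
    """Bundle of aligned panel inputs as consumed by the pipeline stages."""

    expression: OmicsMatrix
    cnv: OmicsMatrix
    mutations: MutationTable
    response: ResponseMatrix
    fingerprints: FingerprintMatrix
    annotation: PanelAnnotation


# ---------------------------------------------------------------------------
# preprocessing operations


def to_pic50(ic50_molar: float, *, from_nanomolar: bool = False) -> float:
    """Convert an IC50 concentration to pIC50 = -log10(IC50 in molar).

    ``from_nanomolar=True`` accepts a nM concentration and still returns the
    molar-based pIC50 (pIC50_M = pIC50_nM + 9).
    """
    if not ic50_molar > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_molar}")
    molar = ic50_molar * 1e-9 if from_nanomolar else ic50_molar
    return -math.log10(molar)


def filter_drugs_by_missingness(
    r: ResponseMatrix, max_missing_fraction: float = 0.40
) -> ResponseMatrix:
    """Keep only drugs whose unobserved fraction is <= ``max_missing_fraction``.

    The boundary is inclusive: a drug missing exactly the threshold fraction
    is retained (the rule removes strictly greater missingness only).
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = r.missing_fraction_per_drug()
    keep = frac <= max_missing_fraction
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_drugs_by_missingness: removed %d of %d drugs", removed, r.n_drugs)
    drug_ids = [d for d, k in zip(r.drug_ids, keep) if k]
    return ResponseMatrix(drug_ids, list(r.cell_line_ids), r.values[keep], r.observed[keep])


def align_panels(parts: Iterable[object]) -> list[object]:
    """Restrict all containers to the common cell-line set, in lexicographic order.

    Accepts any mix of OmicsMatrix / ResponseMatrix / PanelAnnotation (and
    passes MutationTable / FingerprintMatrix through untouched, as neither
    has a dense cell-line axis to restrict).
    """
    parts = list(parts)
    id_sets = []
    for p in parts:
        if isinstance(p, (OmicsMatrix, ResponseMatrix)):
            id_sets.append(set(p.cell_line_ids))
        elif isinstance(p, PanelAnnotation):
            id_sets.append(set(p.cancer_type))
    if not id_sets:
        return parts
    common = set.intersection(*id_sets)
    if not common:
        raise AlignmentError("containers share no cell line ids")
    order = sorted(common)
    dropped = sorted(set.union(*id_sets) - common)
    if dropped:
        logger.info("align_panels: dropped %d cell line(s): %s ...", len(dropped), dropped[:5])
    out: list[object] = []
    for p in parts:
        if isinstance(p, (OmicsMatrix, ResponseMatrix)):
            out.append(p.restrict_cells(order))
        elif isinstance(p, PanelAnnotation):
            out.append(
                PanelAnnotation(
                    {c: t for c, t in p.cancer_type.items() if c in common},
                    dict(p.drug_targets),
                )
            )
        else:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
                         dtype=str)
    except pd.errors.ParserError as e:  # ragged rows and friends
        raise FormatError(f"{path}: {e}") from e
    _check_unique(list(df.index), "row")
    _check_unique(list(df.columns), "column")
    return df


def _to_float(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    try:
        return df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as e:
        raise FormatError(f"{path}: non-numeric cell in numeric matrix ({e})") from e


def read_matrix(path: str | Path, kind: str) -> OmicsMatrix | ResponseMatrix | FingerprintMatrix:
    """Read a TSV matrix as the requested container kind.

    kind: "expression" | "cnv" | "response" | "fingerprint".  Empty cells
    (or "NA") are allowed only in response matrices, where they become
    unobserved entries.
    """
    df = _read_tsv(path)
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if kind == "response":
        df = df.replace("", np.nan)
        vals = _to_float(df, path)
        observed = np.isfinite(vals)
        vals = np.where(observed, vals, 0.0)
        return ResponseMatrix(ids, cols, vals, observed)
    if (df == "").any().any() or df.isna().any().any():
        raise FormatError(f"{path}: empty cells allowed only in response matrices")
    vals = _to_float(df, path)
    if kind in ("expression", "cnv"):
        return OmicsMatrix(kind, ids, cols, vals)
    if kind == "fingerprint":
        return FingerprintMatrix(ids, vals)
    raise ValueError(f"unknown matrix kind {kind!r}")


def read_mutations(path: str | Path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "cell_line", "effect_class"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return MutationTable(df[["gene", "cell_line", "effect_class"]])


def read_annotation(
    path: str | Path, targets_path: str | Path | None = None
) -> PanelAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"cell_line", "cancer_type"} - set(df.columns):
        raise FormatError(f"{path}: need columns cell_line, cancer_type")
    if df["cell_line"].duplicated().any():
        raise FormatError(f"{path}: a cell line is annotated more than once")
    ann = PanelAnnotation(dict(zip(df["cell_line"], df["cancer_type"])))
    if targets_path is not None:
        tdf = pd.read_csv(targets_path, sep="\t", dtype=str)
        if {"drug", "target"} - set(tdf.columns):
            raise FormatError(f"{targets_path}: need columns drug, target")
        ann.drug_targets = {
            d: frozenset(g["target"]) for d, g in tdf.groupby("drug", sort=True)
        }
    return ann


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file into a mapping set name -> unique member gene set."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, >=1 member")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = sorted(set(sets[name]))
            fh.write("\t".join([name, "na", *members]) + "\n")
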