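"""Core domain types and I/O for drug-drug interaction data.

The in-memory model is deliberately small: a :class:`DrugIndex` maps drug
identifier strings to matrix rows, and four thin matrix wrappers
(:class:`InteractionMatrix`, :class:`FeatureMatrix`, :class:`KernelMatrix`,
:class:`PredictionMatrix`) carry a numpy array together with the index and
enforce their structural invariants (symmetry, zero diagonal, binarity,
value ranges).

File formats are plain text: edge lists are two-column CSV/TSV (one
undirected interacting pair per line), feature tables are CSV/TSV with a
``drug_id`` first column and 0/1 feature columns.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateDrugError,
    EmptyTableError,
    NonBinaryValueError,
    SelfInteractionError,
    UnknownDrugError,
)

__all__ = [
    "DrugIndex",
    "InteractionMatrix",
    "FeatureMatrix",
    "KernelMatrix",
    "PredictionMatrix",
    "read_edge_list",
    "write_edge_list",
    "read_feature_table",
    "align",
    "write_ranked_pairs",
    "atomic_write_text",
]


def _sniff_delimiter(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def atomic_write_text(path: str, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    tmp = f"{path}.tmp.{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


@dataclass(frozen=True)
class DrugIndex:
    """Ordered set of N unique drug identifiers with id <-> row lookup."""

    ids: tuple[str, ...]
    _lookup: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lookup: dict[str, int] = {}
        for pos, drug in enumerate(self.ids):
            if not drug:
                raise DuplicateDrugError("empty drug identifier")
            if drug in lookup:
                raise DuplicateDrugError(f"duplicate drug identifier: {drug!r}")
            lookup[drug] = pos
        object.__setattr__(self, "_lookup", lookup)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "DrugIndex":
        return cls(tuple(ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, drug: str) -> bool:
        return drug in self._lookup

    def index(self, drug: str) -> int:
        try:
            return self._lookup[drug]
        except KeyError:
            raise UnknownDrugError(f"unknown drug identifier: {drug!r}") from None

    def union(self, other: "DrugIndex") -> "DrugIndex":
        """Union of two indexes in deterministic sorted order."""
        return DrugIndex(tuple(sorted(set(self.ids) | set(other.ids))))


def _check_square(values: np.ndarray, index: DrugIndex, name: str) -> None:
    n = len(index)
    if values.shape != (n, n):
        raise ValueError(f"{name}: shape {values.shape} does not match index size {n}")


@dataclass
class InteractionMatrix:
    """Symmetric zero-diagonal matrix Y of interaction labels/scores.

    ``binary`` flags a matrix of known 0/1 interactions; after the KNN
    cold-start fill the matrix becomes real-valued and the flag drops.
    """

    values: np.ndarray
    drug_index: DrugIndex
    binary: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_square(self.values, self.drug_index, "InteractionMatrix")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("InteractionMatrix must be symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("InteractionMatrix must have a zero diagonal")
        if self.binary and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary InteractionMatrix has entries outside {0, 1}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_index)

    def known_pairs(self) -> np.ndarray:
        """Unordered known pairs as an (m, 2) array of row indices i < j."""
        iu, ju = np.triu_indices(self.n_drugs, k=1)
        mask = self.values[iu, ju] != 0
        return np.column_stack([iu[mask], ju[mask]])

    def degrees(self) -> np.ndarray:
        return (self.values != 0).sum(axis=1)

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(self.values.copy(), self.drug_index, self.binary)


@dataclass
class FeatureMatrix:
    """N x F binary feature table (chemical/biological/phenotypic bits).

    ``missing`` flags drugs that were absent from the source table and were
    padded with an all-zero row during alignment; the KNN cold-start refuses
    to impute for such drugs.
    """

    values: np.ndarray
    drug_index: DrugIndex
    feature_names: Optional[tuple[str, ...]] = None
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(len(self.drug_index), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.drug_index)
        if self.values.ndim != 2 or self.values.shape[0] != n:
            raise ValueError("FeatureMatrix row count must equal drug index size")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise NonBinaryValueError("FeatureMatrix entries must be 0 or 1")
        if self.feature_names is not None and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must equal feature count")
        if self.missing.shape != (n,):
            raise ValueError("missing flag length must equal drug index size")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class KernelMatrix:
    """Symmetric N x N drug-drug similarity matrix.

    ``kind`` is ``"gip"`` (Gaussian interaction-profile kernel, entries in
    (0, 1], unit diagonal) or ``"pearson"`` (feature correlation, entries in
    [-1, 1]; constant-feature rows are flagged ``degenerate`` and zeroed).
    """

    values: np.ndarray
    drug_index: DrugIndex
    kind: str
    degenerate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.drug_index), dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        self.validate()

    def validate(self) -> None:
        _check_square(self.values, self.drug_index, "KernelMatrix")
        if self.kind not in ("gip", "pearson"):
            raise ValueError(f"unknown kernel kind: {self.kind!r}")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("KernelMatrix must be symmetric")
        if self.kind == "gip":
            # mathematically entries are strictly positive; 0 is tolerated so
            # exp underflow and limiting test kernels (e.g. identity) validate
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise ValueError("GIP kernel entries must lie in [0, 1]")
            if not np.all(np.diagonal(self.values) == 1.0):
                raise ValueError("GIP kernel diagonal must be exactly 1")
        else:
            if np.any(self.values < -1) or np.any(self.values > 1):
                raise ValueError("Pearson similarity entries must lie in [-1, 1]")
            ok = ~self.degenerate
            if not np.all(np.diagonal(self.values)[ok] == 1.0):
                raise ValueError("Pearson diagonal must be 1 for non-degenerate rows")


@dataclass
class PredictionMatrix:
    """Symmetric matrix of predicted interaction scores."""

    values: np.ndarray
    drug_index: DrugIndex

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_square(self.values, self.drug_index, "PredictionMatrix")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("PredictionMatrix must be symmetric")
        if not np.isfinite(self.values).all():
            raise ValueError("PredictionMatrix entries must be finite")


def read_edge_list(
    path: str,
    drug_ids: Optional[DrugIndex] = None,
    header: bool = False,
    delimiter: Optional[str] = None,
) -> InteractionMatrix:
    """Read an undirected edge list into a binary interaction matrix.

    Each data line names one interacting pair; both orderings and duplicate
    lines collapse to a single edge.  Self-pairs are rejected.  When
    ``drug_ids`` is supplied, every identifier must belong to it and drugs
    without edges get all-zero rows; otherwise the index is the sorted set
    of identifiers seen in the file.
    """
    delim = delimiter or _sniff_delimiter(path)
    edges: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or all(not tok.strip() for tok in row):
                continue
            if len(row) < 2:
                raise EmptyTableError(f"line {lineno}: expected two identifiers, got {row!r}")
            a, b = row[0].strip(), row[1].strip()
            if a == b:
                raise SelfInteractionError(f"line {lineno}: self-interaction {a!r}")
            edges.append((a, b))

    if drug_ids is None:
        seen = sorted({d for pair in edges for d in pair})
        if not seen:
            raise EmptyTableError(f"{path}: empty edge list and no drug index supplied")
        drug_ids = DrugIndex.from_ids(seen)

    n = len(drug_ids)
    values = np.zeros((n, n))
    for a, b in edges:
        i, j = drug_ids.index(a), drug_ids.index(b)
        values[i, j] = values[j, i] = 1.0
    return InteractionMatrix(values, drug_ids, binary=True)


def write_edge_list(interactions: InteractionMatrix, path: str) -> None:
    """Write known pairs (i < j, one per line) as a 2-column CSV/TSV."""
    delim = _sniff_delimiter(path)
    ids = interactions.drug_index.ids
    lines = [f"{ids[i]}{delim}{ids[j]}" for i, j in interactions.known_pairs()]
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_feature_table(path: str, header: bool = True) -> FeatureMatrix:
    """Read a CSV/TSV feature table: first column drug id, rest 0/1 bits."""
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, header=0 if header else None, dtype=str)
    if df.shape[0] == 0:
        raise EmptyTableError(f"{path}: feature table has no data rows")
    if df.shape[1] < 2:
        raise EmptyTableError(f"{path}: feature table needs at least one feature column")

    ids = [str(v).strip() for v in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise DuplicateDrugError(f"{path}: duplicated drug id(s): {dupes}")

    raw = df.iloc[:, 1:]
    cells = np.char.strip(raw.to_numpy(dtype=str))
    bad = ~np.isin(cells, ("0", "1"))
    if bad.any():
        row, col = map(int, np.argwhere(bad)[0])
        raise NonBinaryValueError(
            f"{path}: non-binary cell {cells[row, col]!r} at data row {row + 1}, "
            f"feature column {col + 1}"
        )
    values = cells.astype(float)

    names = tuple(str(c) for c in raw.columns) if header else None
    return FeatureMatrix(values, DrugIndex.from_ids(ids), feature_names=names)


def align(
    interactions: InteractionMatrix, features: FeatureMatrix
) -> tuple[InteractionMatrix, FeatureMatrix]:
    """Re-index both matrices onto the sorted union of their drug sets.

    Drugs missing from either side get all-zero rows; feature rows added
    this way are flagged ``missing`` so the cold-start step can skip them.
    """
    union = interactions.drug_index.union(features.drug_index)
    n = len(union)

    y = np.zeros((n, n))
    src = interactions.drug_index
    rows = np.array([union.index(d) for d in src.ids])
    y[np.ix_(rows, rows)] = interactions.values

    f = np.zeros((n, features.n_features))
    missing = np.ones(n, dtype=bool)
    for drug in features.drug_index.ids:
        pos = union.index(drug)
        f[pos] = features.values[features.drug_index.index(drug)]
        missing[pos] = False
    old_missing = dict(zip(features.drug_index.ids, features.missing))
    for drug, was_missing in old_missing.items():
        if was_missing:
            missing[union.index(drug)] = True

    return (
        InteractionMatrix(y, union, binary=interactions.binary),
        FeatureMatrix(f, union, feature_names=features.feature_names, missing=missing),
    )


def ranked_candidate_pairs(
    pred: PredictionMatrix, known: InteractionMatrix, top: Optional[int] = None
) -> list[tuple[str, str, float]]:
    """Candidate pairs (not known to interact) sorted by descending score.

    Ties broken lexicographically by (drug_id_1, drug_id_2).
    """
    if pred.drug_index.ids != known.drug_index.ids:
        raise UnknownDrugError("prediction and known matrices use different drug indexes")
    ids = pred.drug_index.ids
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = known.values[iu, ju] == 0
    rows = [(ids[i], ids[j], float(pred.values[i, j])) for i, j in zip(iu[mask], ju[mask])]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows if top is None else rows[:top]


def write_ranked_pairs(
    pred: PredictionMatrix, known: InteractionMatrix, path: str, top: int
) -> None:
    """Write the top candidate pairs as TSV: rank, drug ids, score (6 dp)."""
    rows = ranked_candidate_pairs(pred, known, top)
    out = ["rank\tdrug_id_1\tdrug_id_2\tscore"]
    for rank, (a, b, s) in enumerate(rows, start=1):
        out.append(f"{rank}\t{a}\t{b}\t{s:.6f}")
    atomic_write_text(path, "\n".join(out) + "\n")
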