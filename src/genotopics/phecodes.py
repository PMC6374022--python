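"""ICD-to-phecode mapping and construction of the binary phenome matrix.

Phecodes aggregate ICD billing codes into clinically meaningful disease
groups; the phenome of a cohort is summarised as a sparse binary matrix X
(individuals x phecodes) with X[i, j] = 1 iff individual i carries at least
one diagnosis code mapping to phecode j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "PhecodeMap",
    "PhenotypeMatrix",
    "load_phecode_map",
    "build_matrix",
    "read_matrix",
    "write_matrix",
]


@dataclass
class PhecodeMap:
    """Many-to-many mapping from ICD code strings to phecode strings.

    ``entries`` maps each ICD code to the set of phecodes it contributes to;
    an ICD code may map to several phecodes and several ICD codes may share
    a phecode.  ``__len__`` counts distinct (icd, phecode) pairs.
    """

    entries: dict[str, frozenset[str]]
    version: str = "unversioned"

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def lookup(self, icd_code: str) -> frozenset[str]:
        return self.entries.get(icd_code.strip(), frozenset())


@dataclass
class PhenotypeMatrix:
    """Sparse binary individual x phecode matrix with row/column labels."""

    X: sp.csr_matrix
    individual_ids: list[str]
    phecodes: list[str]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        n, m = self.X.shape
        if n != len(self.individual_ids):
            raise FormatError(
                f"matrix has {n} rows but {len(self.individual_ids)} individual ids"
            )
        if m != len(self.phecodes):
            raise FormatError(
                f"matrix has {m} columns but {len(self.phecodes)} phecode labels"
            )
        if len(set(self.individual_ids)) != n:
            raise FormatError("individual ids are not unique")
        if len(set(self.phecodes)) != m:
            raise FormatError("phecode labels are not unique")
        if self.X.nnz and (self.X.data.min() < 0 or self.X.data.max() > 1):
            raise FormatError("matrix entries must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def density(self) -> float:
        n, m = self.X.shape
        return self.X.nnz / (n * m)

    def column_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.phecodes)}


def load_phecode_map(path: str | Path, version: str | None = None) -> PhecodeMap:
    """Read a phecode map CSV with (at least) columns ``icd9`` and ``phecode``.

    Duplicate rows are collapsed; whitespace around codes is trimmed.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("icd9", "phecode"):
        if col not in df.columns:
            raise FormatError(f"phecode map {path} lacks required column '{col}'")
    entries: dict[str, set[str]] = {}
    for icd, phe in zip(df["icd9"], df["phecode"]):
        if pd.isna(icd) or pd.isna(phe):
            continue
        icd, phe = str(icd).strip(), str(phe).strip()
        if not icd or not phe:
            raise FormatError("empty ICD code or phecode in map")
        entries.setdefault(icd, set()).add(phe)
    return PhecodeMap(
        entries={k: frozenset(v) for k, v in entries.items()},
        version=version or str(path),
    )


def build_matrix(
    records: Iterable[tuple[str, str]], phecode_map: PhecodeMap
) -> PhenotypeMatrix:
    """Binarize coded-diagnosis records into an individual x phecode matrix.

    ``records`` is an iterable of (individual_id, icd_code).  X[i, j] = 1 iff
    individual i has at least one record mapping to phecode j; repeated codes
    do not accumulate.  ICD codes absent from the map are dropped (with a
    logged count) and individuals left with zero mapped records are excluded:
    an all-zero row is uninformative for the factorization and would have no
    defined topic assignment.  Rows follow first appearance of each retained
    individual; columns are lexicographic over the phecodes observed.
    """
    records = list(records)
    if not records:
        raise DegenerateInputError("no diagnosis records supplied")

    pairs: dict[str, set[str]] = {}
    order: list[str] = []
    n_unmapped = 0
    for ind, icd in records:
        ind = str(ind).strip()
        mapped = phecode_map.lookup(str(icd))
        if not mapped:
            n_unmapped += 1
            continue
        if ind not in pairs:
            pairs[ind] = set()
            order.append(ind)
        pairs[ind].update(mapped)
    if n_unmapped:
        logger.info("dropped %d records with unmapped ICD codes", n_unmapped)
    if not pairs:
        raise DegenerateInputError("all records had unmapped ICD codes")

    phecodes = sorted({p for s in pairs.values() for p in s})
    col = {p: j for j, p in enumerate(phecodes)}
    rows, cols = [], []
    for i, ind in enumerate(order):
        for p in pairs[ind]:
            rows.append(i)
            cols.append(col[p])
    X = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(order), len(phecodes)),
    )
    return PhenotypeMatrix(X=X, individual_ids=order, phecodes=phecodes)


def _read_labels(path: Path) -> list[str]:
    labels = [line.rstrip("\n") for line in path.read_text().splitlines() if line.strip()]
    if not labels:
        raise FormatError(f"label file {path} is empty")
    return labels


def write_matrix(pm: PhenotypeMatrix, out_dir: str | Path, stem: str = "X") -> None:
    """Write MatrixMarket + row/column label TSVs (one label per line)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / f"{stem}.mtx", sp.coo_matrix(pm.X))
    (out / f"{stem}.individuals.tsv").write_text("\n".join(pm.individual_ids) + "\n")
    (out / f"{stem}.phecodes.tsv").write_text("\n".join(pm.phecodes) + "\n")


def read_matrix(in_dir: str | Path, stem: str = "X") -> PhenotypeMatrix:
    """Inverse of :func:`write_matrix`; label/dimension mismatch is an error."""
    in_dir = Path(in_dir)
    X = sp.csr_matrix(mmread(in_dir / f"{stem}.mtx"))
    ids = _read_labels(in_dir / f"{stem}.individuals.tsv")
    phecodes = _read_labels(in_dir / f"{stem}.phecodes.tsv")
    if X.shape != (len(ids), len(phecodes)):
        raise FormatError(
            f"matrix shape {X.shape} does not match labels "
            f"({len(ids)} individuals, {len(phecodes)} phecodes)"
        )
    X.data = np.minimum(X.data, 1).astype(np.int8)
    return PhenotypeMatrix(X=X, individual_ids=ids, phecodes=phecodes)
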