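"""Tab-separated matrix and gene-list formats.

The tool consumes and produces three plain-text formats:

* **Membership TSV** — binary category-by-gene incidence matrix. Line 1 is
  ``category`` followed by TAB-joined gene identifiers; each body row is a
  category name followed by TAB-joined ``0``/``1`` cells. Row *i* is the gene
  set of category *i*.
* **FDR TSV** — category-by-experiment matrix of false-discovery rates in
  ``[0, 1]``, same layout with experiment labels in the header.
* **Gene list** — one identifier per line; blank lines and ``#`` comments are
  ignored. Used to supply a "total genes" test universe.

Canonical in-memory orientation is categories-as-rows; transposed input is
handled at read time via the ``orientation`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("goclique")

__all__ = [
    "FormatError",
    "ValidationError",
    "MembershipMatrix",
    "FDRMatrix",
    "GeneUniverse",
    "read_membership",
    "read_fdr",
    "read_gene_list",
    "write_matrix",
]

REAL_DECIMALS = 6  # declared round-trip precision for real-valued matrices


class FormatError(ValueError):
    """Structural problem in an input file (bad header, duplicates, bad cell)."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic invariant (range, empty row)."""


def _check_labels(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab == "":
            raise FormatError(f"empty {what} label")
        if lab in seen:
            raise FormatError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class MembershipMatrix:
    """Binary categories x genes incidence table.

    ``values[i, j] == 1`` iff gene *j* belongs to category *i*. Every category
    row carries at least one 1; labels are unique and non-empty.
    """

    category_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray  # int8, shape (n_categories, n_genes)

    def __post_init__(self) -> None:
        _check_labels(self.category_ids, "category")
        _check_labels(self.gene_ids, "gene")
        vals = np.asarray(self.values)
        if vals.shape != (len(self.category_ids), len(self.gene_ids)):
            raise ValidationError(
                f"shape {vals.shape} does not match "
                f"{len(self.category_ids)} categories x {len(self.gene_ids)} genes"
            )
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"non-0/1 cell {vals[i, j]!r} at category {self.category_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        empty = np.flatnonzero(vals.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"empty category row: {self.category_ids[int(empty[0])]!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_set(self, category: str) -> frozenset[str]:
        """Gene set of one category (a row of the incidence table)."""
        i = self.category_ids.index(category)
        return frozenset(
            g for g, v in zip(self.gene_ids, self.values[i]) if v
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.category_ids),
            columns=list(self.gene_ids),
        )


@dataclass(frozen=True)
class FDRMatrix:
    """Categories x experiments matrix of per-experiment FDR values in [0, 1]."""

    category_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]
    values: np.ndarray  # float64

    def __post_init__(self) -> None:
        _check_labels(self.category_ids, "category")
        _check_labels(self.experiment_ids, "experiment")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.category_ids), len(self.experiment_ids)):
            raise ValidationError("FDR matrix shape does not match labels")
        if not np.all((vals >= 0.0) & (vals <= 1.0)):
            i, j = map(int, np.argwhere((vals < 0) | (vals > 1))[0])
            raise ValidationError(
                f"FDR value {vals[i, j]} outside [0,1] at category "
                f"{self.category_ids[i]!r}, experiment {self.experiment_ids[j]!r}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.category_ids),
            columns=list(self.experiment_ids),
        )


@dataclass(frozen=True)
class GeneUniverse:
    """The test universe for the overlap contingency tables.

    ``mode="changed"`` restricts the universe to the genes of the membership
    matrix itself (genes mapped to at least one significant category);
    ``mode="all"`` uses an externally supplied total-genes list, which must be
    a superset of the matrix genes.
    """

    gene_ids: frozenset[str]
    mode: Literal["changed", "all"]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError("empty gene universe")
        if self.mode not in ("changed", "all"):
            raise ValidationError(f"unknown universe mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_membership(cls, m: MembershipMatrix) -> "GeneUniverse":
        return cls(gene_ids=frozenset(m.gene_ids), mode="changed")

    def check_contains(self, m: MembershipMatrix) -> None:
        """Validate the mode invariant against a companion membership matrix."""
        genes = frozenset(m.gene_ids)
        if self.mode == "changed" and self.gene_ids != genes:
            raise ValidationError(
                "mode=changed universe must equal the membership matrix genes"
            )
        if self.mode == "all" and not genes <= self.gene_ids:
            missing = sorted(genes - self.gene_ids)[:5]
            raise ValidationError(
                f"mode=all universe misses membership genes: {missing}"
            )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: missing header line")
    # pandas mangles duplicate header labels, so check them on the raw line
    _check_labels([c.strip() for c in header.rstrip("\n").split("\t")[1:]], "column")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no categories (empty body)")
    return df


def read_membership(
    path: str | Path,
    orientation: Literal["categories-as-rows", "genes-as-rows"] = "categories-as-rows",
) -> MembershipMatrix:
    """Read a binary membership TSV into the canonical categories-as-rows layout.

    Parameters
    ----------
    path
        Tab-separated file; first row a header of column identifiers, each body
        row a label plus 0/1 cells.
    orientation
        ``"genes-as-rows"`` transposes the file content on read.
    """
    df = _read_table(path)
    if orientation == "genes-as-rows":
        df = df.T
    elif orientation != "categories-as-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    cats = [str(c) for c in df.index]
    genes = [str(g) for g in df.columns]
    _check_labels(cats, "category")
    _check_labels(genes, "gene")

    vals = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell == "0":
                vals[i, j] = 0
            elif cell == "1":
                vals[i, j] = 1
            else:
                raise FormatError(
                    f"non-0/1 cell {cell!r} at category {cats[i]!r}, gene {genes[j]!r}"
                )
    return MembershipMatrix(tuple(cats), tuple(genes), vals)


def read_fdr(path: str | Path) -> FDRMatrix:
    """Read a category-by-experiment FDR TSV (floats in [0, 1])."""
    df = _read_table(path)
    cats = [str(c) for c in df.index]
    exps = [str(e) for e in df.columns]
    _check_labels(cats, "category")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric FDR cell ({exc})") from exc
    return FDRMatrix(tuple(cats), tuple(exps), vals)


def read_gene_list(path: str | Path) -> GeneUniverse:
    """Read a total-genes list (one identifier per line) as a mode=all universe.

    Blank lines and lines starting with ``#`` are skipped; duplicates are
    dropped with a logged warning each.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        gid = line.strip()
        if not gid or gid.startswith("#"):
            continue
        if gid in seen:
            logger.warning("duplicate gene identifier in %s: %s", path, gid)
            continue
        seen.add(gid)
        genes.append(gid)
    if not genes:
        raise ValidationError(f"{path}: empty gene list")
    return GeneUniverse(gene_ids=frozenset(genes), mode="all")


def write_matrix(m, path: str | Path) -> Path:
    """Write any matrix object to tab-separated text.

    Binary matrices (membership, META CIM) round-trip bit-exactly; real-valued
    matrices (FDR, reduced CIMs, similarity) are written with 6 decimal places.
    Accepts :class:`MembershipMatrix`, :class:`FDRMatrix`, or any object with a
    ``to_frame()`` method (reduced/META CIMs, similarity matrices).
    """
    path = Path(path)
    df = m.to_frame()
    binary = df.to_numpy().dtype.kind in "iub"
    with open(path, "w") as fh:
        fh.write("\t".join(["category", *(str(c) for c in df.columns)]) + "\n")
        for label, row in zip(df.index, df.to_numpy()):
            if binary:
                cells = [str(int(v)) for v in row]
            else:
                cells = [f"{float(v):.{REAL_DECIMALS}f}" for v in row]
            fh.write("\t".join([str(label), *cells]) + "\n")
    return path
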