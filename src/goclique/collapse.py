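"""Merge clustered categories into reduced-CIM rows and build the META CIM.

Each cluster becomes one output row. The merge rule depends on the matrix
kind: binary category-versus-gene membership rows are **averaged** (a cell
becomes the fraction of group members containing that gene), while
category-versus-experiment FDR rows take the **minimum** (a group is as
significant as its best member). Singleton groups pass through unchanged.

Multi-member groups are displayed as ``<representative>:<N>`` where N is the
1-based group index; the full member list lives in a sidecar mapping. The
META CIM is the binary categories-by-group matrix restricted to multi-member
groups: a row with two 1s is a category serving two distinct functional
contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io_formats import FDRMatrix, MembershipMatrix, ValidationError
from .multiclust import ClusterSet

logger = logging.getLogger("goclique")

__all__ = [
    "MergedGroup",
    "ReducedCIM",
    "MetaCIM",
    "name_groups",
    "collapse_membership",
    "collapse_fdr",
    "apply_clusters",
    "build_meta_cim",
    "compression_ratio",
]


@dataclass(frozen=True)
class MergedGroup:
    """A named de-replicated group: representative label plus full membership."""

    index: int
    representative: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValidationError("representative must be a group member")

    @property
    def display_name(self) -> str:
        """``rep:N`` for merged groups; singletons keep their bare name."""
        if len(self.members) >= 2:
            return f"{self.representative}:{self.index}"
        return self.representative

    @property
    def concatenated_name(self) -> str:
        """All member names joined — kept for the sidecar mapping."""
        return ";".join(sorted(self.members))


@dataclass(frozen=True)
class ReducedCIM:
    """Collapsed output matrix: one row per group, values per the merge rule."""

    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    values: np.ndarray
    kind: Literal["membership", "fdr"]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValidationError("reduced CIM shape does not match labels")
        if vals.size and not np.all((vals >= 0) & (vals <= 1)):
            raise ValidationError("reduced CIM values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.row_labels),
            columns=list(self.column_labels),
        )


@dataclass(frozen=True)
class MetaCIM:
    """Binary categories-by-group membership for multi-member groups only."""

    row_labels: tuple[str, ...]  # categories in >=1 multi-member group
    column_labels: tuple[str, ...]  # group_<N> for each multi-member group
    values: np.ndarray  # 0/1

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValidationError("META CIM shape does not match labels")
        if vals.size:
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("META CIM cells must be 0/1")
            if (vals.sum(axis=1) < 1).any():
                raise ValidationError("every META CIM row needs >=1 membership")
            if (vals.sum(axis=0) < 2).any():
                raise ValidationError("every META CIM column needs >=2 members")
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def is_empty(self) -> bool:
        return len(self.column_labels) == 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.row_labels),
            columns=list(self.column_labels),
        )


def name_groups(cs: ClusterSet, f: FDRMatrix | None = None) -> list[MergedGroup]:
    """Assign 1-based indices and pick each group's representative member.

    The representative is the member with the smallest minimum FDR across
    experiments when an FDR matrix is supplied (the most significant member is
    the most informative label), otherwise the lexicographically first member;
    FDR ties break lexicographically.
    """
    min_fdr: dict[str, float] = {}
    if f is not None:
        mins = f.values.min(axis=1)
        min_fdr = dict(zip(f.category_ids, mins.astype(float)))

    groups: list[MergedGroup] = []
    for c in cs.clusters:
        members = sorted(c.members)
        if min_fdr:
            rep = min(members, key=lambda m: (min_fdr.get(m, np.inf), m))
        else:
            rep = members[0]
        groups.append(
            MergedGroup(index=c.index, representative=rep, members=c.members)
        )
    return groups


def _rows_by_label(category_ids: tuple[str, ...]) -> dict[str, int]:
    return {c: i for i, c in enumerate(category_ids)}


def _collapse(
    category_ids: tuple[str, ...],
    values: np.ndarray,
    groups: list[MergedGroup],
    reducer,
    kind: Literal["membership", "fdr"],
    column_labels: tuple[str, ...],
) -> ReducedCIM:
    row_of = _rows_by_label(category_ids)
    out_rows: list[np.ndarray] = []
    labels: list[str] = []
    for g in groups:
        missing = [m for m in g.members if m not in row_of]
        if missing:
            raise ValidationError(
                f"group {g.index} references unknown categories: {sorted(missing)}"
            )
        block = values[[row_of[m] for m in sorted(g.members)]]
        out_rows.append(reducer(block))
        labels.append(g.display_name)
    return ReducedCIM(
        row_labels=tuple(labels),
        column_labels=column_labels,
        values=np.vstack(out_rows) if out_rows else np.empty((0, len(column_labels))),
        kind=kind,
    )


def collapse_membership(
    m: MembershipMatrix, cs: ClusterSet, groups: list[MergedGroup] | None = None
) -> ReducedCIM:
    """Average member rows per group: cells become fractional gene membership."""
    if groups is None:
        groups = name_groups(cs)
    return _collapse(
        m.category_ids,
        m.values.astype(float),
        groups,
        lambda block: block.mean(axis=0),
        "membership",
        m.gene_ids,
    )


def collapse_fdr(
    f: FDRMatrix, cs: ClusterSet, groups: list[MergedGroup] | None = None
) -> ReducedCIM:
    """Take the per-experiment minimum FDR over each group's member rows."""
    if groups is None:
        groups = name_groups(cs, f)
    return _collapse(
        f.category_ids,
        f.values,
        groups,
        lambda block: block.min(axis=0),
        "fdr",
        f.experiment_ids,
    )


def apply_clusters(
    m: MembershipMatrix | FDRMatrix,
    cs: ClusterSet,
    groups: list[MergedGroup] | None = None,
) -> ReducedCIM:
    """Collapse a matrix with an externally derived grouping pattern.

    This is the default-mode contract: the pattern from the integrative matrix
    is applied to each individual matrix. Members absent from the matrix are
    dropped from their group for this matrix (logged); groups emptied by the
    drops are omitted.
    """
    if groups is None:
        groups = name_groups(cs, m if isinstance(m, FDRMatrix) else None)
    present = set(m.category_ids)
    pruned: list[MergedGroup] = []
    for g in groups:
        kept = g.members & present
        if not kept:
            logger.warning("group %d absent from matrix; omitted", g.index)
            continue
        if kept != g.members:
            logger.warning(
                "group %d: dropping absent members %s",
                g.index,
                sorted(g.members - kept),
            )
            rep = g.representative if g.representative in kept else sorted(kept)[0]
            g = MergedGroup(index=g.index, representative=rep, members=frozenset(kept))
        pruned.append(g)
    if isinstance(m, FDRMatrix):
        return collapse_fdr(m, cs, pruned)
    return collapse_membership(m, cs, pruned)


def build_meta_cim(cs: ClusterSet) -> MetaCIM:
    """Binary categories x multi-member-group matrix showing the merge pattern.

    Columns carry the same group indices as the ``:N`` suffixes of the reduced
    CIM, so a row with several 1s identifies a category shared between
    functional contexts. All-singleton cluster sets yield an empty META CIM.
    """
    multi = cs.multi_member_clusters
    cats = sorted(set().union(*(c.members for c in multi)) if multi else set())
    vals = np.zeros((len(cats), len(multi)), dtype=np.int8)
    row_of = {c: i for i, c in enumerate(cats)}
    for j, c in enumerate(multi):
        for m in c.members:
            vals[row_of[m], j] = 1
    return MetaCIM(
        row_labels=tuple(cats),
        column_labels=tuple(f"group_{c.index}" for c in multi),
        values=vals,
    )


def compression_ratio(n_input_categories: int, n_output_rows: int) -> float:
    """Input category count over reduced-CIM row count, to 2 decimals."""
    if n_output_rows < 1:
        raise ValidationError("cannot compute a compression ratio with zero output rows")
    return round(n_input_categories / n_output_rows, 2)
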