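"""Hierarchical row/column ordering and heatmap rendering for CIM output.

Ordering is agglomerative average-linkage (UPGMA) on Euclidean distances
between rows (or columns), so identical merged rows sit adjacent and the
broad block structure of the matrix is visible. The leaf order is made
deterministic by always placing the subtree containing the smaller original
index first. Reordering only permutes labels; cell values are untouched.

Rendering follows the membership-CIM colour convention — 0 yellow, 1 red,
fractional values in between — with a continuous colormap for FDR matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import linkage

from .collapse import MetaCIM
from .io_formats import MembershipMatrix, ValidationError

logger = logging.getLogger("goclique")

__all__ = [
    "DendrogramOrder",
    "hierarchical_order",
    "render_heatmap",
    "filter_large_categories",
]


@dataclass(frozen=True)
class DendrogramOrder:
    """Leaf permutations plus the merge history for each clustered axis."""

    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    row_linkage: np.ndarray | None  # scipy linkage matrix or None (axis not clustered)
    col_linkage: np.ndarray | None

    def __post_init__(self) -> None:
        for name, order in (("row_order", self.row_order), ("col_order", self.col_order)):
            if sorted(order) != list(range(len(order))):
                raise ValidationError(f"{name} is not a permutation")


def _leaf_order(z: np.ndarray, n: int) -> tuple[int, ...]:
    # deterministic traversal: subtree holding the smaller original index first
    children: dict[int, tuple[int, int]] = {
        n + i: (int(z[i, 0]), int(z[i, 1])) for i in range(z.shape[0])
    }

    min_leaf_cache: dict[int, int] = {}

    def fill(node: int) -> int:
        if node < n:
            min_leaf_cache[node] = node
            return node
        a, b = children[node]
        m = min(fill(a), fill(b))
        min_leaf_cache[node] = m
        return m

    root = n + z.shape[0] - 1
    fill(root)

    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = (a, b) if min_leaf_cache[a] <= min_leaf_cache[b] else (b, a)
        stack.append(second)
        stack.append(first)
    return tuple(order)


def _axis_linkage(mat: np.ndarray) -> tuple[tuple[int, ...], np.ndarray | None]:
    n = mat.shape[0]
    if n <= 1:
        return tuple(range(n)), None
    z = linkage(mat, method="average", metric="euclidean")
    return _leaf_order(z, n), z


def _as_array(matrix) -> np.ndarray:
    if hasattr(matrix, "values"):
        return np.asarray(matrix.values, dtype=float)
    return np.asarray(matrix, dtype=float)


def hierarchical_order(
    matrix, axes: Literal["rows", "cols", "both"] = "both"
) -> DendrogramOrder:
    """UPGMA (average linkage, Euclidean) ordering of rows and/or columns."""
    mat = _as_array(matrix)
    if mat.ndim != 2 or mat.shape[0] < 1 or mat.shape[1] < 1:
        raise ValidationError("need at least one row and one column to order")
    row_order: tuple[int, ...] = tuple(range(mat.shape[0]))
    col_order: tuple[int, ...] = tuple(range(mat.shape[1]))
    row_z = col_z = None
    if axes in ("rows", "both"):
        row_order, row_z = _axis_linkage(mat)
    if axes in ("cols", "both"):
        col_order, col_z = _axis_linkage(mat.T)
    return DendrogramOrder(
        row_order=row_order, col_order=col_order, row_linkage=row_z, col_linkage=col_z
    )


def render_heatmap(matrix, order: DendrogramOrder | None, path: str | Path) -> Path | None:
    """Render a matrix as a PNG heatmap; returns the path, or None if empty.

    Membership-style matrices use a yellow-to-red scale (0 yellow, 1 red);
    FDR matrices use a continuous perceptual colormap. An empty META CIM
    produces no file, only a logged notice.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(matrix, MetaCIM) and matrix.is_empty:
        logger.info("META CIM is empty (no multi-member groups); nothing to render")
        return None
    df = matrix.to_frame() if hasattr(matrix, "to_frame") else matrix
    if order is not None:
        df = df.iloc[list(order.row_order), list(order.col_order)]

    kind = getattr(matrix, "kind", "membership")
    cmap = "viridis_r" if kind == "fdr" else "autumn_r"  # autumn_r: 0 yellow -> 1 red

    h = max(2.0, 0.22 * df.shape[0] + 1.5)
    w = max(3.0, 0.22 * df.shape[1] + 2.5)
    fig, ax = plt.subplots(figsize=(w, h), dpi=100)
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap=cmap, vmin=0.0, vmax=1.0)
    ax.set_xticks(range(df.shape[1]), labels=[str(c) for c in df.columns],
                  rotation=90, fontsize=5)
    ax.set_yticks(range(df.shape[0]), labels=[str(r) for r in df.index], fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="png", metadata={"Software": ""})
    plt.close(fig)
    return path


def filter_large_categories(m: MembershipMatrix, max_genes: int) -> MembershipMatrix:
    """Drop very large generic categories (gene count above ``max_genes``).

    Huge catch-all categories dominate a CIM without adding interpretive
    value; this optional filter removes them before similarity is computed.
    """
    if max_genes < 1:
        raise ValidationError("max_genes must be >= 1")
    sizes = m.values.sum(axis=1)
    keep = sizes <= max_genes
    if not keep.any():
        raise ValidationError("size filter removed every category")
    dropped = [c for c, k in zip(m.category_ids, keep) if not k]
    for c in dropped:
        logger.info("size filter: dropping category %r", c)
    if not dropped:
        return m
    return MembershipMatrix(
        category_ids=tuple(c for c, k in zip(m.category_ids, keep) if k),
        gene_ids=m.gene_ids,
        values=m.values[keep],
    )
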