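"""Threshold selection, category graph, and greedy maximal-clique clustering.

The user steers stringency through a *nominal number of merged pairs*: the
count of category pairs whose pairwise p-value passes the chosen threshold.
:func:`select_threshold` converts that count into a p-value cutoff (the
target-th smallest off-diagonal p-value); ties at the cutoff admit every tied
pair, so the achieved count can exceed the nominal one.

:func:`build_graph` connects two categories when their p-value is at or below
the cutoff (smaller p = more similar). :func:`multiclust` then grows clusters
under a complete-linkage rule — a category joins a cluster only if it is
connected to every current member — iterated to a fixpoint from one singleton
cluster per category, followed by deduplication and strict-subset pruning.
Every surviving cluster is a maximal clique of the graph, every category is
covered, and a category may legitimately belong to several clusters: that
multi-membership is the point of the method, read off later from the META CIM.

Vertices and clusters are always visited in lexicographic category-name order,
so the output is a deterministic function of the graph alone, invariant under
input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import ValidationError
from .overlap_stats import SimilarityMatrix

__all__ = [
    "CategoryGraph",
    "CategoryCluster",
    "ClusterSet",
    "DecompositionReport",
    "select_threshold",
    "build_graph",
    "multiclust",
    "verify_decomposition",
]


@dataclass(frozen=True)
class CategoryGraph:
    """Undirected graph over categories; an edge marks a pair passing the cutoff."""

    graph: nx.Graph
    p_threshold: float

    @property
    def vertices(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, v: str) -> frozenset[str]:
        return frozenset(self.graph.neighbors(v))


@dataclass(frozen=True)
class CategoryCluster:
    """One de-replicated functional group: a maximal clique of the category graph."""

    members: frozenset[str]
    index: int  # 1-based, assigned in canonical order

    def __len__(self) -> int:
        return len(self.members)

    @property
    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass(frozen=True)
class ClusterSet:
    """MultiClust output: maximal cliques covering every category."""

    clusters: tuple[CategoryCluster, ...]
    reference: tuple[str, ...]  # the full significant-category list
    achieved_pairs: int  # edges in the source graph

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def member_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(c.members for c in self.clusters)

    @property
    def multi_member_clusters(self) -> tuple[CategoryCluster, ...]:
        return tuple(c for c in self.clusters if len(c) >= 2)


def select_threshold(
    s: SimilarityMatrix, target_pairs: int
) -> tuple[float, int]:
    """Translate a nominal merged-pairs count into a p-value cutoff.

    The cutoff is the ``target_pairs``-th smallest off-diagonal p-value; the
    achieved count is the number of pairs at or below it, which can exceed the
    nominal count under ties. ``target_pairs=0`` yields a cutoff of 0 (no pair
    can pass, since every p-value is positive).
    """
    if target_pairs < 0:
        raise ValidationError("target_pairs must be non-negative")
    tri = np.sort(s.upper_triangle())
    if target_pairs > tri.size:
        raise ValidationError(
            f"target_pairs={target_pairs} exceeds the {tri.size} available pairs"
        )
    if target_pairs == 0:
        return 0.0, 0
    p_threshold = float(tri[target_pairs - 1])
    achieved = int(np.count_nonzero(tri <= p_threshold))
    return p_threshold, achieved


def build_graph(s: SimilarityMatrix, p_threshold: float) -> CategoryGraph:
    """Connect category pairs whose Fisher p-value is at or below the cutoff."""
    g = nx.Graph()
    g.add_nodes_from(s.category_ids)
    n = s.n
    for i in range(n):
        for j in range(i + 1, n):
            if s.p_values[i, j] <= p_threshold:
                g.add_edge(s.category_ids[i], s.category_ids[j])
    return CategoryGraph(graph=g, p_threshold=float(p_threshold))


def _canonical_clusters(member_sets: set[frozenset[str]]) -> list[frozenset[str]]:
    # drop strict subsets (non-maximal artifacts of the growth schedule)
    kept = [
        c
        for c in member_sets
        if not any(c < other for other in member_sets)
    ]
    return sorted(kept, key=lambda c: tuple(sorted(c)))


def multiclust(g: CategoryGraph) -> ClusterSet:
    """Grow complete-linkage clusters to a fixpoint; return the clique cover.

    Every category seeds its own singleton cluster. Repeatedly, each cluster
    absorbs any category adjacent to all of its members; the sweep restarts
    until a full pass makes no change. Identical clusters are merged, strict
    subsets pruned, and the survivors indexed 1..K in canonical
    (lexicographic member-tuple) order.
    """
    vertices = list(g.vertices)  # sorted
    adj = {v: g.neighbors(v) for v in vertices}

    clusters: list[set[str]] = [{v} for v in vertices]
    change = True
    while change:
        change = False
        for c in clusters:
            for ref in vertices:
                if ref in c:
                    continue
                if all(ref in adj[m] for m in c):
                    c.add(ref)
                    change = True
        # keep the current set of unique clusters
        unique: list[set[str]] = []
        seen: set[frozenset[str]] = set()
        for c in clusters:
            key = frozenset(c)
            if key not in seen:
                seen.add(key)
                unique.append(c)
        clusters = unique

    canon = _canonical_clusters({frozenset(c) for c in clusters})
    return ClusterSet(
        clusters=tuple(
            CategoryCluster(members=c, index=i)
            for i, c in enumerate(canon, start=1)
        ),
        reference=tuple(vertices),
        achieved_pairs=g.n_edges,
    )


@dataclass(frozen=True)
class DecompositionReport:
    """Structured pass/fail record for a clique-cover decomposition."""

    clique_failures: tuple[str, ...] = ()
    maximality_failures: tuple[str, ...] = ()
    uncovered: tuple[str, ...] = ()
    subset_or_duplicate: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not (
            self.clique_failures
            or self.maximality_failures
            or self.uncovered
            or self.subset_or_duplicate
        )

    def summary(self) -> str:
        if self.passed:
            return "decomposition OK"
        lines = ["decomposition FAILED"]
        for name in (
            "clique_failures",
            "maximality_failures",
            "uncovered",
            "subset_or_duplicate",
        ):
            for msg in getattr(self, name):
                lines.append(f"  {name}: {msg}")
        return "\n".join(lines)


def verify_decomposition(g: CategoryGraph, cs: ClusterSet) -> DecompositionReport:
    """Check clique-ness, maximality, vertex cover and subset-freeness.

    Maximality is checked by intersecting member neighborhoods: a cluster is
    maximal iff no outside vertex is adjacent to all members.
    """
    adj = {v: g.neighbors(v) for v in g.vertices}
    clique_failures: list[str] = []
    maximality_failures: list[str] = []
    subset_or_duplicate: list[str] = []

    sets = [c.members for c in cs.clusters]
    for c in cs.clusters:
        members = c.sorted_members
        bad_pair = next(
            (
                (a, b)
                for ai, a in enumerate(members)
                for b in members[ai + 1 :]
                if b not in adj[a]
            ),
            None,
        )
        if bad_pair:
            clique_failures.append(f"cluster {c.index}: non-adjacent pair {bad_pair}")
        common = frozenset(g.vertices)
        for m in c.members:
            common &= adj[m]
        extenders = common - c.members
        if extenders:
            maximality_failures.append(
                f"cluster {c.index}: extendable by {sorted(extenders)}"
            )
        others = [s for s in sets if s is not c.members]
        if any(c.members <= s for s in others):
            subset_or_duplicate.append(
                f"cluster {c.index}: subset or duplicate of another cluster"
            )

    covered = frozenset().union(*sets) if sets else frozenset()
    uncovered = sorted(frozenset(g.vertices) - covered)
    return DecompositionReport(
        clique_failures=tuple(clique_failures),
        maximality_failures=tuple(maximality_failures),
        uncovered=tuple(uncovered),
        subset_or_duplicate=tuple(subset_or_duplicate),
    )
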