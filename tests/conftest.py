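import numpy as np
import pytest

from goclique import (
    CategoryCluster,
    CategoryGraph,
    ClusterSet,
    FDRMatrix,
    GeneUniverse,
    MembershipMatrix,
)
import networkx as nx


def membership_from_rows(rows: dict[str, str]) -> MembershipMatrix:
    """Build a MembershipMatrix from {'cat': '0110', ...} bit-strings."""
    cats = tuple(rows)
    n_genes = len(next(iter(rows.values())))
    genes = tuple(f"g{j + 1}" for j in range(n_genes))
    vals = np.array([[int(c) for c in bits] for bits in rows.values()], dtype=np.int8)
    return MembershipMatrix(cats, genes, vals)


def graph_from_edges(vertices, edges) -> CategoryGraph:
    g = nx.Graph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges)
    return CategoryGraph(graph=g, p_threshold=0.05)


def cluster_set(member_sets, vertices=None, achieved_pairs=0) -> ClusterSet:
    sets = [frozenset(s) for s in member_sets]
    if vertices is None:
        vertices = sorted(set().union(*sets))
    return ClusterSet(
        clusters=tuple(
            CategoryCluster(members=s, index=i) for i, s in enumerate(sets, 1)
        ),
        reference=tuple(sorted(vertices)),
        achieved_pairs=achieved_pairs,
    )


@pytest.fixture
def small_membership() -> MembershipMatrix:
    """3 categories x 4 genes; catA and catB overlap heavily, catC is apart."""
    return membership_from_rows(
        {"catA": "1101", "catB": "1100", "catC": "0011"}
    )


@pytest.fixture
def small_fdr() -> FDRMatrix:
    return FDRMatrix(
        category_ids=("catA", "catB", "catC"),
        experiment_ids=("exp1", "exp2"),
        values=np.array([[0.01, 0.5], [0.09, 1.0], [0.2, 0.001]]),
    )


@pytest.fixture
def universe10() -> GeneUniverse:
    return GeneUniverse(frozenset(f"g{i}" for i in range(1, 11)), mode="all")
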