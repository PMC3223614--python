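"""Synthetic membership/FDR matrices with planted redundant category groups.

Real enrichment output is redundant because near-identical gene sets map to
many related GO categories. The generator emulates exactly that structure:
each planted group shares a disjoint core of genes, each member category adds
per-gene noise ("jitter": the probability that a non-core cell flips to 1),
and independent background categories are sprinkled in at a low density.
Because the cores are gene-disjoint across groups, the ground-truth grouping
is unambiguous and recovery can be scored exactly.

Defaults mirror the scale of typical enrichment post-processing runs: a
~120-gene universe, 4 planted groups of 3 categories around 8-gene cores,
2% jitter, 10 background categories at 5% density, 3 experiments. FDR values
are decorative (uniform in [0, 0.1], i.e. uniformly significant) since the
pipeline only min-pools them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import FDRMatrix, MembershipMatrix, ValidationError
from .multiclust import ClusterSet

__all__ = [
    "PlantedDesign",
    "PlantedTruth",
    "generate_planted",
    "recovery_score",
]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of a planted-redundancy simulation."""

    n_genes: int = 120
    n_groups: int = 4
    group_size: int = 3
    core_genes_per_group: int = 8
    jitter: float = 0.02
    n_background: int = 10
    background_density: float = 0.05
    n_experiments: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_genes_per_group < 1:
            raise ValidationError("core_genes_per_group must be >= 1")
        for name in ("jitter", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_groups * self.core_genes_per_group > self.n_genes:
            raise ValidationError(
                "infeasible design: disjoint cores exceed the gene universe"
            )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulation: category-to-group map and per-group cores."""

    group_assignments: dict[str, int]  # planted category -> 1-based group index
    core_gene_sets: dict[int, frozenset[str]]

    @property
    def planted_groups(self) -> dict[int, frozenset[str]]:
        """Group index -> the set of member category names."""
        out: dict[int, set[str]] = {}
        for cat, g in self.group_assignments.items():
            out.setdefault(g, set()).add(cat)
        return {g: frozenset(cats) for g, cats in out.items()}


def generate_planted(
    d: PlantedDesign,
) -> tuple[MembershipMatrix, FDRMatrix, PlantedTruth]:
    """Simulate a membership matrix with planted near-identical category groups.

    Each planted category is its group's core genes plus jittered extras;
    background categories are sampled independently (re-drawn if empty, since
    empty categories never occur in enrichment output). Fully reproducible
    from the design seed.
    """
    rng = np.random.default_rng(d.seed)
    genes = tuple(f"gene_{i:04d}" for i in range(d.n_genes))

    core_cols: dict[int, np.ndarray] = {}
    perm = rng.permutation(d.n_genes)
    for g in range(1, d.n_groups + 1):
        lo = (g - 1) * d.core_genes_per_group
        core_cols[g] = np.sort(perm[lo : lo + d.core_genes_per_group])

    rows: list[np.ndarray] = []
    cats: list[str] = []
    assignments: dict[str, int] = {}
    for g in range(1, d.n_groups + 1):
        core_mask = np.zeros(d.n_genes, dtype=np.int8)
        core_mask[core_cols[g]] = 1
        for k in range(1, d.group_size + 1):
            row = core_mask.copy()
            flips = (rng.random(d.n_genes) < d.jitter) & (core_mask == 0)
            row[flips] = 1
            name = f"grp{g:02d}_cat{k}"
            rows.append(row)
            cats.append(name)
            assignments[name] = g

    for k in range(1, d.n_background + 1):
        while True:
            row = (rng.random(d.n_genes) < d.background_density).astype(np.int8)
            if row.any():
                break
        rows.append(row)
        cats.append(f"bg{k:02d}")

    m = MembershipMatrix(
        category_ids=tuple(cats), gene_ids=genes, values=np.vstack(rows)
    )
    f = FDRMatrix(
        category_ids=tuple(cats),
        experiment_ids=tuple(f"exp_{e}" for e in range(1, d.n_experiments + 1)),
        values=rng.uniform(0.0, 0.1, size=(len(cats), d.n_experiments)),
    )
    truth = PlantedTruth(
        group_assignments=assignments,
        core_gene_sets={
            g: frozenset(genes[i] for i in cols) for g, cols in core_cols.items()
        },
    )
    return m, f, truth


def recovery_score(cs: ClusterSet, truth: PlantedTruth) -> float:
    """Fraction of planted groups recovered exactly (set equality) as a cluster.

    A truth with zero planted groups scores 1.0 vacuously.
    """
    planted = truth.planted_groups
    if not planted:
        return 1.0
    found = set(cs.member_sets)
    hits = sum(1 for members in planted.values() if members in found)
    return hits / len(planted)
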