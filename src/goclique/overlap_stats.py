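"""Pairwise category-overlap similarity via the one-tail Fisher's exact test.

Two GO categories are redundant when nearly the same genes map to both. The
similarity score for a pair is the one-tail (over-representation) Fisher's
exact p-value of their gene-set overlap: the probability, under the
hypergeometric null of independent draws from a shared gene universe, of an
intersection at least as large as the one observed. Small p means strongly
shared genes. Because the test conditions on both set sizes, two large dense
gene sets do not score as similar unless their overlap exceeds what their
sizes alone predict.

The p-value is computed exactly for all table sizes by accumulating
hypergeometric terms in log space (log-gamma factorials); no normal or
chi-square approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import GeneUniverse, MembershipMatrix, ValidationError

__all__ = [
    "ContingencyTable",
    "SimilarityMatrix",
    "build_contingency",
    "fisher_one_tail",
    "pairwise_similarity",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table between two gene sets drawn from one universe.

    ``n11`` genes in both categories, ``n10`` in the first only, ``n01`` in the
    second only, ``n00`` in neither; the four cells partition the universe.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def size_a(self) -> int:
        """Size of the first category."""
        return self.n11 + self.n10

    @property
    def size_b(self) -> int:
        """Size of the second category."""
        return self.n11 + self.n01

    @property
    def universe_size(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def build_contingency(
    set_a: Iterable[str], set_b: Iterable[str], universe: GeneUniverse
) -> ContingencyTable:
    """Partition the universe into the four overlap cells for two gene sets."""
    a = frozenset(set_a)
    b = frozenset(set_b)
    if not a or not b:
        raise ValidationError("category gene sets must be non-empty")
    stray = (a | b) - universe.gene_ids
    if stray:
        raise ValidationError(
            f"genes outside the universe: {sorted(stray)[:10]}"
        )
    n11 = len(a & b)
    n10 = len(a) - n11
    n01 = len(b) - n11
    n00 = len(universe) - n11 - n10 - n01
    return ContingencyTable(n11=n11, n10=n10, n01=n01, n00=n00)


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_one_tail(t: ContingencyTable) -> float:
    """Over-representation tail P(X >= n11) of the hypergeometric null.

    With both category sizes and the universe size fixed, X is the overlap of
    two independent random subsets:
    ``P(X = k) = C(Ka, k) C(N-Ka, Kb-k) / C(N, Kb)``. The tail is accumulated
    term by term in log space and never exceeds 1.
    """
    if t.n11 == 0:
        return 1.0  # the tail spans the whole support
    N = t.universe_size
    ka, kb = t.size_a, t.size_b
    k_min = t.n11
    k_max = min(ka, kb)
    log_denom = _log_binom(N, kb)
    log_terms = [
        _log_binom(ka, k) + _log_binom(N - ka, kb - k) - log_denom
        for k in range(k_min, k_max + 1)
        if kb - k <= N - ka  # infeasible overlap has zero probability
    ]
    if not log_terms:
        return 0.0
    m = max(log_terms)
    p = exp(m) * sum(exp(t_ - m) for t_ in log_terms)
    return min(p, 1.0)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric matrix of pairwise one-tail Fisher p-values between categories.

    The diagonal is undefined (NaN) and excluded from every pair enumeration.
    """

    category_ids: tuple[str, ...]
    p_values: np.ndarray  # float64, symmetric, NaN diagonal

    def __post_init__(self) -> None:
        n = len(self.category_ids)
        p = np.asarray(self.p_values, dtype=float)
        if p.shape != (n, n):
            raise ValidationError("similarity matrix must be square over categories")
        off = ~np.eye(n, dtype=bool)
        if n > 1 and not np.allclose(p[off], p.T[off], rtol=0, atol=0):
            raise ValidationError("similarity matrix must be symmetric")
        if n > 1 and not np.all((p[off] > 0) & (p[off] <= 1)):
            raise ValidationError("off-diagonal p-values must lie in (0, 1]")
        object.__setattr__(self, "p_values", p)

    @property
    def n(self) -> int:
        return len(self.category_ids)

    def pair_p(self, a: str, b: str) -> float:
        i = self.category_ids.index(a)
        j = self.category_ids.index(b)
        if i == j:
            raise ValueError("diagonal entries are not pairs")
        return float(self.p_values[i, j])

    def upper_triangle(self) -> np.ndarray:
        """All n(n-1)/2 off-diagonal p-values, one per unordered pair."""
        iu = np.triu_indices(self.n, k=1)
        return self.p_values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.p_values.copy(),
            index=list(self.category_ids),
            columns=list(self.category_ids),
        )


def pairwise_similarity(
    m: MembershipMatrix, universe: GeneUniverse | None = None
) -> SimilarityMatrix:
    """One-tail Fisher p-value for every unordered pair of categories.

    When ``universe`` is omitted the mode=changed universe (the genes of the
    matrix itself) is used. Overlap counts come from the incidence matrix
    product; each pair's p-value is computed exactly.
    """
    if len(m.category_ids) < 2:
        raise ValidationError("nothing to compare: need at least 2 categories")
    if universe is None:
        universe = GeneUniverse.from_membership(m)
    universe.check_contains(m)

    n = len(m.category_ids)
    N = len(universe)
    inc = m.values.astype(np.int64)
    overlap = inc @ inc.T  # n11 for every pair
    sizes = inc.sum(axis=1)

    p = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            t = ContingencyTable(
                n11=int(overlap[i, j]),
                n10=int(sizes[i] - overlap[i, j]),
                n01=int(sizes[j] - overlap[i, j]),
                n00=int(N - sizes[i] - sizes[j] + overlap[i, j]),
            )
            p[i, j] = p[j, i] = fisher_one_tail(t)
    return SimilarityMatrix(category_ids=m.category_ids, p_values=p)
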