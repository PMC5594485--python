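"""Hierarchical clustering with Pearson correlation distance and complete linkage.

Differentially regulated probes are clustered on their per-genotype log2
fold-change profiles (or, transposed, genotypes on their probe profiles) with
distance d = 1 - r, r the Pearson correlation, and complete (maximum)
linkage. Complete linkage is monotone, so merge heights never decrease.

The agglomeration is an explicit O(n^3) loop rather than a library call so
the tie-break is fully specified: among equally distant cluster pairs, the
pair whose (smallest-leaf, smallest-leaf) index tuple is lexicographically
least merges first. scipy's linkage is used as an independent cross-check on
tie-free inputs in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "Dendrogram", "pearson_distance", "complete_linkage"]


@dataclass
class DistanceMatrix:
    items: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.items)
        if self.d.shape != (n, n):
            raise ValueError("distance grid shape does not match item count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance grid must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance grid must have zero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class Dendrogram:
    """Merge list in scipy convention: leaves are nodes 0..n-1, the k-th merge
    creates node n+k from (left, right) at the given height."""

    items: list[str]
    merges: list[tuple[int, int, float, int]]  # (left, right, height, size)
    leaf_order: list[str]


def pearson_distance(profiles: pd.DataFrame) -> DistanceMatrix:
    """1 - Pearson correlation between rows of ``profiles``.

    Rows are items (probes or genotypes), columns the coordinates of each
    profile (length >= 2). A zero-variance row has undefined correlation and
    raises, naming the item.
    """
    X = profiles.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("profiles need length >= 2")
    sd = X.std(axis=1)
    flat = [str(profiles.index[i]) for i in np.nonzero(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance profile(s): {flat}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(items=[str(i) for i in profiles.index], d=d)


def complete_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative complete-linkage clustering with deterministic ties.

    At each step the active cluster pair with minimal maximum inter-point
    distance merges; ties resolve to the lexicographically smallest pair of
    smallest-leaf indices. Heights are non-decreasing (complete linkage is
    monotone).
    """
    n = len(dist.items)
    if n < 2:
        raise ValueError("clustering needs at least 2 items")
    d = dist.d.astype(float).copy()

    # active clusters: node id -> (min leaf index, set of leaves)
    active: dict[int, tuple[int, frozenset[int]]] = {
        i: (i, frozenset([i])) for i in range(n)
    }
    # cluster-level distances, keyed by frozen node-id pair
    cd: dict[frozenset[int], float] = {
        frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    while len(active) > 1:
        best = None
        for pair, dij in cd.items():
            a, b = sorted(pair, key=lambda nid: active[nid][0])
            key = (dij, active[a][0], active[b][0])
            if best is None or key < best[0]:
                best = (key, a, b)
        (height, _, _), a, b = best
        leaves = active[a][1] | active[b][1]
        merges.append((a, b, float(height), len(leaves)))
        children[next_id] = (a, b)
        new_min = min(active[a][0], active[b][0])
        for other in list(active):
            if other in (a, b):
                continue
            cd[frozenset((next_id, other))] = max(
                cd.pop(frozenset((a, other))), cd.pop(frozenset((b, other)))
            )
        cd.pop(frozenset((a, b)))
        del active[a], active[b]
        active[next_id] = (new_min, leaves)
        next_id += 1

    order: list[str] = []

    def _walk(node: int) -> None:
        if node < n:
            order.append(dist.items[node])
        else:
            left, right = children[node]
            _walk(left)
            _walk(right)

    _walk(next_id - 1)
    return Dendrogram(items=list(dist.items), merges=merges, leaf_order=order)
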