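"""Brute-force validation backend for the Rips homology pipeline.

Independent of the production path in :mod:`conntda.tda`: Betti numbers
are computed directly from ranks of the simplicial boundary matrices of
the thresholded clique 2-skeleton over GF(2),

    B0(eps) = N - rank d1,   B1(eps) = (E - rank d1) - rank d2,

with E the number of edges at threshold eps. Exponential in nothing but
still cubic-ish in simplex counts, so meant for small N only.
"""

from __future__ import annotations

import itertools

import numpy as np


def _rank_gf2(columns: list[int]) -> int:
    """Rank of a GF(2) matrix given as bitmask columns."""
    pivots: dict[int, int] = {}
    rank = 0
    for col in columns:
        while col:
            p = col.bit_length() - 1
            other = pivots.get(p)
            if other is None:
                pivots[p] = col
                rank += 1
                break
            col ^= other
    return rank


def betti_numbers_brute(d: np.ndarray, eps: float) -> tuple[int, int]:
    """(B0, B1) of the Rips complex at threshold ``eps`` (edges with
    distance <= eps, triangles with all three edges <= eps)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    edges = [
        (i, j) for i, j in itertools.combinations(range(n), 2) if d[i, j] <= eps
    ]
    eidx = {e: k for k, e in enumerate(edges)}
    d1 = [(1 << i) | (1 << j) for i, j in edges]
    rank1 = _rank_gf2(d1)
    b0 = n - rank1
    d2 = []
    for i, j, k in itertools.combinations(range(n), 3):
        if d[i, j] <= eps and d[i, k] <= eps and d[j, k] <= eps:
            d2.append(
                (1 << eidx[(i, j)]) | (1 << eidx[(i, k)]) | (1 << eidx[(j, k)])
            )
    rank2 = _rank_gf2(d2)
    b1 = (len(edges) - rank1) - rank2
    return b0, b1


def betti_curves_brute(d: np.ndarray, maxscale: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Betti-0/1 at every distinct filtration value <= maxscale
    (plus 0), as (values, b0, b1) arrays."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    w = d[np.triu_indices(n, 1)]
    values = np.unique(np.concatenate([[0.0], w[w <= maxscale]]))
    b0 = np.empty(values.size, dtype=int)
    b1 = np.empty(values.size, dtype=int)
    for k, eps in enumerate(values):
        b0[k], b1[k] = betti_numbers_brute(d, eps)
    return values, b0, b1


def mst_edge_weights(d: np.ndarray) -> np.ndarray:
    """Sorted minimum-spanning-forest edge weights via scipy (oracle for
    the finite degree-0 deaths)."""
    from scipy.sparse.csgraph import minimum_spanning_tree

    d = np.asarray(d, dtype=float)
    mst = minimum_spanning_tree(d).toarray()
    return np.sort(mst[mst > 0.0])
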