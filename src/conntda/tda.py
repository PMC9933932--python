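"""Vietoris-Rips persistent homology of correlation-distance matrices.

The filtration sweeps a distance threshold epsilon from 0 to ``maxscale``;
an edge enters when its distance d = 1 - r falls below epsilon, a triangle
when its longest edge does. Betti-0 counts connected components, Betti-1
independent 1-dimensional holes. Degree-0 persistence comes from Kruskal
union-find (finite deaths are exactly the minimum-spanning-forest edge
weights); degree-1 persistence from GF(2) column reduction of the triangle
boundary matrix restricted to cycle-creating edges (the clearing
optimization: rows of spanning-forest edges can never be pivots, because
the largest edge of any 1-cycle necessarily creates a cycle when it enters
the filtration).

Betti curves, their areas (total persistence) and curve landmarks are the
per-session scalar features fed to the developmental models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import (
    NETWORKS,
    WHOLE_BRAIN,
    DegenerateDistanceError,
    DistanceMatrix,
    Parcellation,
    subset_network,
)

#: Default filtration cap: the theoretical maximum of d = 1 - r.
DEFAULT_MAXSCALE = 2.0


@dataclass
class PersistenceDiagram:
    """Persistence intervals (dim, birth, death), death = +inf for
    classes still alive at ``maxscale``. Zero-persistence pairs are
    omitted (they contribute nothing to any statistic)."""

    intervals: list[tuple[int, float, float]]
    maxscale: float
    n_points: int

    def of_dim(self, dim: int) -> np.ndarray:
        """(k, 2) array of (birth, death) for one dimension."""
        rows = [(b, d) for dd, b, d in self.intervals if dd == dim]
        return np.asarray(rows, dtype=float).reshape(-1, 2)


@dataclass
class BettiCurve:
    """Step function epsilon -> Betti count on an ascending grid."""

    dim: int
    grid: np.ndarray
    counts: np.ndarray
    maxscale: float


@dataclass
class SessionFeatures:
    """Scalar topological summaries of one session x network."""

    session_id: str
    network: str
    b0_auc: float
    b1_auc: float
    n_holes: int
    eps_single: float
    b1_onset: float | None
    b1_offset: float | None
    b1_max: int
    b1_argmax: float | None


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _validate_distance(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        m = d.d
    else:
        m = np.asarray(d, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10, rtol=0.0):
            raise ValueError("distance matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")
    n = m.shape[0]
    if n >= 2 and np.all(m[np.triu_indices(n, 1)] == 0.0):
        raise DegenerateDistanceError(
            "degenerate distance matrix: all off-diagonal distances are 0 "
            "(every node coincides); no filtration to compute"
        )
    return m


def rips_persistence(
    d: DistanceMatrix | np.ndarray,
    maxdim: int = 1,
    maxscale: float = DEFAULT_MAXSCALE,
) -> PersistenceDiagram:
    """Persistence diagram (H0 and H1) of the Rips filtration of ``d``.

    Simplices with filtration value above ``maxscale`` are excluded;
    classes alive at ``maxscale`` are reported with death +inf.
    """
    if maxdim > 1:
        raise NotImplementedError("homology above dimension 1 is not supported")
    if maxscale <= 0:
        raise ValueError("maxscale must be positive")
    m = _validate_distance(d)
    n = m.shape[0]

    iu, ju = np.triu_indices(n, 1)
    w = m[iu, ju]
    within = w <= maxscale
    iu, ju, w = iu[within], ju[within], w[within]
    order = np.lexsort((ju, iu, w))  # by (weight, i, j)
    iu, ju, w = iu[order], ju[order], w[order]

    intervals: list[tuple[int, float, float]] = []

    # --- H0: Kruskal union-find; merge weights are the finite deaths.
    uf = _UnionFind(n)
    positive = np.zeros(w.size, dtype=bool)  # cycle-creating edges
    for k in range(w.size):
        if uf.union(int(iu[k]), int(ju[k])):
            if w[k] > 0.0:  # zero-persistence pairs dropped
                intervals.append((0, 0.0, float(w[k])))
        else:
            positive[k] = True
    n_components = len({uf.find(v) for v in range(n)})
    intervals.extend([(0, 0.0, math.inf)] * n_components)

    if maxdim >= 1 and n >= 3:
        intervals.extend(_h1_intervals(m, iu, ju, w, positive, maxscale))

    return PersistenceDiagram(intervals=intervals, maxscale=float(maxscale), n_points=n)


def _h1_intervals(m, iu, ju, w, positive, maxscale):
    """Degree-1 pairs by GF(2) reduction of the triangle boundary matrix
    restricted to positive (cycle-creating) edge rows."""
    n = m.shape[0]
    # bit position of each positive edge in filtration order
    pos_bit = -np.ones((n, n), dtype=np.int64)
    births = []
    for k in np.flatnonzero(positive):
        b = len(births)
        pos_bit[iu[k], ju[k]] = b
        pos_bit[ju[k], iu[k]] = b
        births.append(float(w[k]))
    if not births:
        return []

    tri = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 3)),
        dtype=np.int64,
    ).reshape(-1, 3)
    ti, tj, tk = tri[:, 0], tri[:, 1], tri[:, 2]
    tval = np.maximum(np.maximum(m[ti, tj], m[ti, tk]), m[tj, tk])
    keep = tval <= maxscale
    tri, tval = tri[keep], tval[keep]
    torder = np.lexsort((tri[:, 2], tri[:, 1], tri[:, 0], tval))
    tri, tval = tri[torder], tval[torder]
    b1 = pos_bit[tri[:, 0], tri[:, 1]]
    b2 = pos_bit[tri[:, 0], tri[:, 2]]
    b3 = pos_bit[tri[:, 1], tri[:, 2]]

    reduced: dict[int, int] = {}  # pivot bit -> reduced column
    death_of: dict[int, float] = {}
    for t in range(tri.shape[0]):
        col = 0
        if b1[t] >= 0:
            col |= 1 << int(b1[t])
        if b2[t] >= 0:
            col |= 1 << int(b2[t])
        if b3[t] >= 0:
            col |= 1 << int(b3[t])
        while col:
            pivot = col.bit_length() - 1
            other = reduced.get(pivot)
            if other is None:
                reduced[pivot] = col
                death_of[pivot] = float(tval[t])
                break
            col ^= other

    out = []
    for bit, birth in enumerate(births):
        death = death_of.get(bit, math.inf)
        if death > birth:
            out.append((1, birth, death))
    return out


def betti_curve(pd: PersistenceDiagram, dim: int, grid: np.ndarray) -> BettiCurve:
    """Betti count on a grid: count(eps) = #{birth <= eps < death}
    (right-continuous steps); essential classes persist through maxscale."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a nonempty 1-d array")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending")
    if grid[0] < 0 or grid[-1] > pd.maxscale + 1e-12:
        raise ValueError("grid must lie within [0, maxscale]")
    ivals = pd.of_dim(dim)
    if ivals.shape[0] == 0:
        counts = np.zeros(grid.size, dtype=int)
    else:
        births = np.sort(ivals[:, 0])
        deaths = np.sort(ivals[np.isfinite(ivals[:, 1]), 1])
        counts = (
            np.searchsorted(births, grid, side="right")
            - np.searchsorted(deaths, grid, side="right")
        )
    return BettiCurve(dim=dim, grid=grid, counts=counts.astype(int), maxscale=pd.maxscale)


def default_grid(maxscale: float = DEFAULT_MAXSCALE, step: float = 0.005) -> np.ndarray:
    """Uniform plotting/landmark grid; statistics never depend on it."""
    n = int(round(maxscale / step))
    return np.linspace(0.0, maxscale, n + 1)


def betti_auc(pd: PersistenceDiagram, dim: int, maxscale: float | None = None) -> float:
    """Area under the Betti curve = total persistence
    sum_i (min(death_i, maxscale) - birth_i)."""
    if maxscale is None:
        maxscale = pd.maxscale
    ivals = pd.of_dim(dim)
    if ivals.shape[0] == 0:
        return 0.0
    deaths = np.minimum(ivals[:, 1], maxscale)
    births = np.minimum(ivals[:, 0], maxscale)
    return float(np.sum(np.maximum(deaths - births, 0.0)))


def count_holes(pd: PersistenceDiagram) -> int:
    """Number of degree-1 intervals with positive persistence."""
    return int(pd.of_dim(1).shape[0])


def curve_landmarks(pd: PersistenceDiagram, maxscale: float | None = None) -> dict:
    """Landmarks of the Betti curves.

    ``eps_single``: filtration value where the component count first
    reaches its terminal value (largest finite H0 death; 0.0 when points
    merge instantly). ``b1_onset``/``b1_offset``: first hole birth / last
    finite hole death. ``b1_max``/``b1_argmax``: peak hole count and the
    smallest filtration attaining it. B1 landmarks are None when the
    diagram has no holes.
    """
    if maxscale is None:
        maxscale = pd.maxscale
    h0 = pd.of_dim(0)
    finite0 = h0[np.isfinite(h0[:, 1]), 1]
    eps_single = float(finite0.max()) if finite0.size else 0.0
    h1 = pd.of_dim(1)
    if h1.shape[0] == 0:
        return {
            "eps_single": eps_single,
            "b1_onset": None,
            "b1_offset": None,
            "b1_max": 0,
            "b1_argmax": None,
        }
    births = np.sort(h1[:, 0])
    finite1 = np.sort(h1[np.isfinite(h1[:, 1]), 1])
    # the step function only increases at births; evaluate there
    counts_at_births = (
        np.searchsorted(births, births, side="right")
        - np.searchsorted(finite1, births, side="right")
    )
    k = int(np.argmax(counts_at_births))
    return {
        "eps_single": eps_single,
        "b1_onset": float(births[0]),
        "b1_offset": float(finite1[-1]) if finite1.size else None,
        "b1_max": int(counts_at_births[k]),
        "b1_argmax": float(births[k]),
    }


def session_features(
    d: DistanceMatrix,
    p: Parcellation,
    maxscale: float = DEFAULT_MAXSCALE,
    session_id: str = "session",
) -> list[SessionFeatures]:
    """Whole-brain plus per-network topological features of one session.

    Produces one row for the whole-brain matrix (label "ALL") and one for
    every functional network with at least 3 ROIs present in ``d``.
    """
    rows = []
    for label in (WHOLE_BRAIN, *NETWORKS):
        if label != WHOLE_BRAIN:
            present = [r for r in p.members(label) if r in set(d.roi_ids)]
            if len(present) < 3:
                continue
        sub = subset_network(d, p, label)
        pd_ = rips_persistence(sub, maxdim=1, maxscale=maxscale)
        lm = curve_landmarks(pd_)
        rows.append(
            SessionFeatures(
                session_id=session_id,
                network=label,
                b0_auc=betti_auc(pd_, 0),
                b1_auc=betti_auc(pd_, 1),
                n_holes=count_holes(pd_),
                eps_single=lm["eps_single"],
                b1_onset=lm["b1_onset"],
                b1_offset=lm["b1_offset"],
                b1_max=lm["b1_max"],
                b1_argmax=lm["b1_argmax"],
            )
        )
    return rows


def features_frame(rows: list[SessionFeatures]):
    """Session-feature rows as a pandas DataFrame."""
    import pandas as pd_

    return pd_.DataFrame([r.__dict__ for r in rows])
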