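"""Edge-rewired bootstrap null distributions of Betti curves.

The null destroys network topology while keeping the edge-weight
distribution: the upper-triangle correlations are uniformly permuted
over node pairs and mirrored. Each bootstrap draws one connectome from
the sample with replacement, rewires it, and records its Betti curve;
the ensemble is summarized by the pointwise mean and 2.5/97.5 percentile
band. A master seed spawns one substream per bootstrap, so truncating or
extending the ensemble never reshuffles earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, to_distance
from .tda import betti_curve, rips_persistence


@dataclass
class NullEnsemble:
    dim: int
    grid: np.ndarray
    mean_curve: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_boot: int
    seed: int


def rewire_connectome(
    c: Connectome, rng: np.random.Generator | None = None
) -> Connectome:
    """Uniformly permute the upper-triangle edge weights over node pairs
    (weight multiset preserved exactly, topology destroyed)."""
    if rng is None:
        rng = np.random.default_rng()
    n = c.n_rois
    iu = np.triu_indices(n, 1)
    vals = c.r[iu]
    perm = rng.permutation(vals.size)
    out = np.eye(n)
    out[iu] = vals[perm]
    out = out + np.triu(out, 1).T
    np.fill_diagonal(out, 1.0)
    return Connectome(r=out, roi_ids=list(c.roi_ids))


def _content_order(connectomes: list[Connectome]) -> list[Connectome]:
    """Stable content-based ordering so ensemble statistics do not
    depend on the order the connectomes were supplied in."""
    import hashlib

    def key(c: Connectome) -> str:
        iu = np.triu_indices(c.n_rois, 1)
        return hashlib.sha256(np.round(c.r[iu], 12).tobytes()).hexdigest()

    return sorted(connectomes, key=key)


def bootstrap_curves(
    connectomes: list[Connectome],
    n_boot: int,
    dim: int,
    grid: np.ndarray,
    seed: int = 0,
    maxscale: float = 2.0,
    rewire: bool = True,
) -> np.ndarray:
    """(n_boot, len(grid)) array of bootstrap Betti curves; bootstrap b
    always uses substream b of the master seed, so extending n_boot
    never changes earlier draws."""
    if not connectomes:
        raise ValueError("need at least one connectome")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    connectomes = _content_order(connectomes)
    grid = np.asarray(grid, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(n_boot)
    curves = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        rng = np.random.default_rng(streams[b])
        c = connectomes[int(rng.integers(len(connectomes)))]
        if rewire:
            c = rewire_connectome(c, rng)
        pd_ = rips_persistence(to_distance(c), maxdim=dim, maxscale=maxscale)
        curves[b] = betti_curve(pd_, dim, grid).counts
    return curves


def null_ensemble(
    connectomes: list[Connectome],
    n_boot: int = 1000,
    dim: int = 1,
    grid: np.ndarray | None = None,
    seed: int = 0,
    maxscale: float = 2.0,
    rewire: bool = True,
) -> NullEnsemble:
    """Bootstrap ensemble of rewired-connectome Betti curves.

    ``rewire=False`` gives the plain resampling ensemble (identity mode,
    useful for checks).
    """
    if grid is None:
        from .tda import default_grid

        grid = default_grid(maxscale)
    grid = np.asarray(grid, dtype=float)
    curves = bootstrap_curves(
        connectomes, n_boot, dim, grid, seed=seed, maxscale=maxscale, rewire=rewire
    )
    return NullEnsemble(
        dim=dim,
        grid=grid,
        mean_curve=curves.mean(axis=0),
        lo95=np.percentile(curves, 2.5, axis=0),
        hi95=np.percentile(curves, 97.5, axis=0),
        n_boot=n_boot,
        seed=seed,
    )
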