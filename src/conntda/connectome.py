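"""Per-session connectome construction and quality control.

Turns ROI time series into Pearson-correlation connectomes and the
correlation distances (d = 1 - r) consumed by the Rips filtration,
including the motion-aware confound expansion (6 rigid-body parameters +
global/white-matter/CSF means -> 36 regressors), spike scrubbing by
framewise displacement, and the minimum-clean-data session rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: The 13 canonical resting-state network labels of the 264-ROI parcellation.
NETWORKS = (
    "AUD", "CBL", "CON", "DMN", "DAN", "FPN", "MEM",
    "SAL", "SMH", "SMM", "SUB", "VAN", "VIS",
)

#: Sentinel network label denoting the whole-brain matrix.
WHOLE_BRAIN = "ALL"

#: Framewise-displacement spike threshold, mm.
DEFAULT_SPIKE_THRESHOLD = 0.25

#: Minimum clean (non-spike) data required to keep a session, minutes.
DEFAULT_MIN_CLEAN_MINUTES = 4.0


class DegenerateDistanceError(ValueError):
    """Raised when a distance matrix has no metric structure to filter
    (all off-diagonal distances zero: every node coincides)."""


def _as_2d_float(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass
class RoiTimeSeries:
    """T x N matrix of per-ROI signals sampled every ``tr`` seconds."""

    data: np.ndarray
    tr: float
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = _as_2d_float(self.data, "time series")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise ValueError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(n)]
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length must match number of columns")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class Parcellation:
    """Mapping from ROI id to one of the 13 functional-network labels."""

    roi_ids: list[str]
    network: list[str]

    def __post_init__(self):
        if len(self.roi_ids) != len(self.network):
            raise ValueError("roi_ids and network must have equal length")
        bad = sorted(set(self.network) - set(NETWORKS))
        if bad:
            raise ValueError(
                f"unknown network labels {bad}; valid labels are {list(NETWORKS)}"
            )
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("duplicate ROI ids in parcellation")

    def members(self, label: str) -> list[str]:
        if label == WHOLE_BRAIN:
            return list(self.roi_ids)
        if label not in NETWORKS:
            raise ValueError(
                f"unknown network label {label!r}; valid labels are "
                f"{[WHOLE_BRAIN, *NETWORKS]}"
            )
        return [r for r, n in zip(self.roi_ids, self.network) if n == label]


def _check_square_symmetric(m: np.ndarray, name: str, tol: float = 1e-10):
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol, rtol=0.0):
        raise ValueError(f"{name} must be symmetric")


@dataclass
class Connectome:
    """N x N Pearson-correlation matrix over ROIs."""

    r: np.ndarray
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.r = _as_2d_float(self.r, "correlation matrix")
        _check_square_symmetric(self.r, "correlation matrix")
        n = self.r.shape[0]
        if np.any(np.abs(self.r) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("correlation diagonal must be 1")
        # normalize numerically exact invariants
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(n)]
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length must match matrix size")

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


@dataclass
class DistanceMatrix:
    """N x N correlation-distance matrix, d = 1 - r in [0, 2]."""

    d: np.ndarray
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.d = _as_2d_float(self.d, "distance matrix")
        _check_square_symmetric(self.d, "distance matrix")
        n = self.d.shape[0]
        if np.any(self.d < -1e-9) or np.any(self.d > 2.0 + 1e-9):
            raise ValueError("distances must lie in [0, 2]")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, 2.0)
        np.fill_diagonal(self.d, 0.0)
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(n)]
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length must match matrix size")

    @property
    def n_rois(self) -> int:
        return self.d.shape[0]


@dataclass
class MotionTrace:
    """Per-volume framewise displacement (mm) at sampling interval ``tr``."""

    fd: np.ndarray
    tr: float

    def __post_init__(self):
        self.fd = np.asarray(self.fd, dtype=float).ravel()
        if self.fd.size == 0:
            raise ValueError("empty motion trace")
        if not np.all(np.isfinite(self.fd)) or np.any(self.fd < 0):
            raise ValueError("framewise displacement must be finite and >= 0")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")


def expand_confounds(base: np.ndarray) -> np.ndarray:
    """Expand the 9 base nuisance signals into the 36-parameter set.

    Rows 0-8 are the base signals (6 motion parameters plus global,
    white-matter and CSF means), rows 9-17 their backward-difference
    temporal derivatives (leading element 0), and rows 18-35 the
    elementwise squares of rows 0-17, in that order.
    """
    base = _as_2d_float(base, "confound base")
    if base.shape[0] != 9:
        raise ValueError(f"expected exactly 9 base confound rows, got {base.shape[0]}")
    if base.shape[1] < 2:
        raise ValueError("confound signals need at least 2 timepoints")
    deriv = np.zeros_like(base)
    deriv[:, 1:] = np.diff(base, axis=1)
    first18 = np.vstack([base, deriv])
    return np.vstack([first18, first18 ** 2])


def qc_session(
    motion: MotionTrace,
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD,
    min_clean: float = DEFAULT_MIN_CLEAN_MINUTES,
) -> dict:
    """Spike mask and keep/discard decision for one session.

    A volume is a spike when FD exceeds ``spike_threshold`` (mm). The
    session passes when the non-spike volumes amount to at least
    ``min_clean`` minutes of data.
    """
    if spike_threshold <= 0:
        raise ValueError("spike_threshold must be positive (mm)")
    if min_clean <= 0:
        raise ValueError("min_clean must be positive (minutes)")
    spike_mask = motion.fd > spike_threshold
    clean_seconds = float(np.count_nonzero(~spike_mask)) * motion.tr
    return {
        "spike_mask": spike_mask,
        "pass_flag": bool(clean_seconds >= min_clean * 60.0),
        "n_spikes": int(spike_mask.sum()),
        "clean_minutes": clean_seconds / 60.0,
    }


def regress_confounds(
    ts: RoiTimeSeries,
    confounds: np.ndarray,
    spike_mask: np.ndarray | None = None,
) -> RoiTimeSeries:
    """OLS residuals of every ROI signal on the confound design.

    The design holds an intercept, the confound rows (transposed to
    columns) and one delta regressor per spike volume. Collinear columns
    are dropped with a logged warning; the residuals are orthogonal to
    the retained design.
    """
    t = ts.n_volumes
    confounds = _as_2d_float(confounds, "confounds")
    if confounds.shape[1] != t:
        raise ValueError(
            f"confound rows span {confounds.shape[1]} timepoints, expected {t}"
        )
    cols = [np.ones((t, 1)), confounds.T]
    if spike_mask is not None:
        spike_mask = np.asarray(spike_mask, dtype=bool).ravel()
        if spike_mask.size != t:
            raise ValueError("spike_mask length must equal T")
        for idx in np.flatnonzero(spike_mask):
            delta = np.zeros((t, 1))
            delta[idx, 0] = 1.0
            cols.append(delta)
    design = np.hstack(cols)
    if design.shape[1] > t:
        raise ValueError(
            f"more regressors ({design.shape[1]}) than timepoints ({t})"
        )
    # rank-revealing QR: drop collinear columns
    q, rmat, piv = _qr_with_pivoting(design)
    rank = int(np.sum(np.abs(np.diag(rmat)) > 1e-10 * max(1.0, abs(rmat[0, 0]))))
    if rank < design.shape[1]:
        logger.warning(
            "confound design rank-deficient: dropped %d collinear column(s)",
            design.shape[1] - rank,
        )
    keep = np.sort(piv[:rank])
    design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return RoiTimeSeries(data=resid, tr=ts.tr, roi_ids=list(ts.roi_ids))


def _qr_with_pivoting(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def pearson_connectome(ts: RoiTimeSeries) -> Connectome:
    """Pearson-correlation connectome of the ROI signals."""
    rng_ = np.ptp(ts.data, axis=0)
    bad = np.flatnonzero(rng_ == 0)
    if bad.size:
        names = [ts.roi_ids[i] for i in bad[:5]]
        raise ValueError(f"constant ROI signal(s), correlation undefined: {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    return Connectome(r=r, roi_ids=list(ts.roi_ids))


def to_distance(c: Connectome) -> DistanceMatrix:
    """Correlation distance d = 1 - r (0 for perfectly coupled nodes,
    2 for perfectly anticorrelated ones)."""
    d = 1.0 - c.r
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, roi_ids=list(c.roi_ids))


def from_distance(d: DistanceMatrix) -> Connectome:
    """Inverse of :func:`to_distance` (r = 1 - d)."""
    r = 1.0 - d.d
    np.fill_diagonal(r, 1.0)
    return Connectome(r=r, roi_ids=list(d.roi_ids))


def subset_network(x, p: Parcellation, network_label: str):
    """Principal submatrix restricted to one functional network.

    The sentinel label ``"ALL"`` returns the input unchanged so that
    whole-brain and per-network analyses share one code path.
    """
    if network_label == WHOLE_BRAIN:
        return x
    members = set(p.members(network_label))
    idx = [i for i, roi in enumerate(x.roi_ids) if roi in members]
    if len(idx) < 3:
        raise ValueError(
            f"network {network_label!r} has {len(idx)} ROI(s) in this matrix; "
            "at least 3 are required for homology"
        )
    idx = np.asarray(idx)
    roi_ids = [x.roi_ids[i] for i in idx]
    if isinstance(x, Connectome):
        return Connectome(r=x.r[np.ix_(idx, idx)], roi_ids=roi_ids)
    if isinstance(x, DistanceMatrix):
        return DistanceMatrix(d=x.d[np.ix_(idx, idx)], roi_ids=roi_ids)
    raise TypeError("expected a Connectome or DistanceMatrix")
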