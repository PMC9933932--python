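"""Gaussian linear mixed models by maximum likelihood, with penalized
splines in their mixed-model representation.

The trajectory battery needs, for every fit: the marginal ML
log-likelihood (AIC), per-term effective degrees of freedom (trace of the
penalized hat contribution), the Bayesian coefficient covariance, and a
Wood-type F test of smooth terms. This module provides a compact dense
solver for models of the form

    y = X beta + sum_j Z_j u_j + e,   u_j ~ N(0, tau_j sigma^2 I),
    e ~ N(0, sigma^2 I),

profiling beta and sigma^2 out of the likelihood and optimizing the
variance ratios tau_j numerically. A penalized cubic B-spline smooth with
second-divided-difference penalty over the Greville abscissae maps onto
one such variance component; its penalty null space ({1, x}, or the
bilinear functions for a tensor product) enters the fixed effects, so a
smooth at the null-space limit (tau -> 0) is exactly linear.

Sizes here are hundreds of observations and tens of random coefficients,
so dense Cholesky factorizations of the n x n marginal covariance are the
fastest honest option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)

_LOGTAU_LO, _LOGTAU_HI = -16.0, 16.0


# ---------------------------------------------------------------------------
# penalized spline bases


def _greville(t: np.ndarray, degree: int) -> np.ndarray:
    """Greville abscissae of a knot vector (coefficient 'sites')."""
    k = len(t) - degree - 1
    return np.array([t[i + 1 : i + degree + 1].mean() for i in range(k)])


def _divdiff2(g: np.ndarray) -> np.ndarray:
    """Second-divided-difference matrix over sites ``g``; its null space
    is exactly the coefficient vectors linear in g."""
    k = g.size
    d = np.zeros((k - 2, k))
    for i in range(k - 2):
        h1 = g[i + 1] - g[i]
        h2 = g[i + 2] - g[i + 1]
        d[i, i] = 1.0 / h1
        d[i, i + 1] = -(1.0 / h1 + 1.0 / h2)
        d[i, i + 2] = 1.0 / h2
    return d


@dataclass
class PSpline1D:
    """Cubic penalized B-spline smooth of one covariate.

    ``transform`` maps covariate values to (fixed, random) design parts:
    the fixed part is the centered covariate itself (the penalty null
    space beyond the intercept), the random part spans the penalized
    wiggle space, scaled so an identity prior matches the penalty.
    """

    k: int = 10
    degree: int = 3
    knots_: np.ndarray | None = None
    x_mean_: float = 0.0
    wiggle_: np.ndarray | None = None  # basis-to-random-coefs map
    lo_: float = 0.0
    hi_: float = 1.0

    def fit(self, x: np.ndarray) -> "PSpline1D":
        x = np.asarray(x, dtype=float)
        distinct = np.unique(x)
        if distinct.size < 3:
            raise ValueError("smooth covariate needs >= 3 distinct values")
        k_eff = min(self.k, distinct.size)
        degree = min(self.degree, k_eff - 1)
        if k_eff != self.k or degree != self.degree:
            logger.warning(
                "smooth basis shrunk to k=%d, degree=%d (covariate has %d "
                "distinct values)", k_eff, degree, distinct.size,
            )
        self.k, self.degree = k_eff, degree
        self.lo_, self.hi_ = float(x.min()), float(x.max())
        span = self.hi_ - self.lo_
        n_interior = k_eff - degree - 1
        interior = np.linspace(self.lo_, self.hi_, n_interior + 2)[1:-1]
        self.knots_ = np.concatenate(
            [np.full(degree + 1, self.lo_), interior, np.full(degree + 1, self.hi_)]
        )
        # guard against zero-span degenerate range
        if span <= 0:
            raise ValueError("smooth covariate has zero range")
        g = _greville(self.knots_, degree)
        s = _divdiff2(g)
        pen = s.T @ s
        lam, u = eigh(pen)
        pos = lam > lam[-1] * 1e-9
        self.wiggle_ = u[:, pos] / np.sqrt(lam[pos])
        self.x_mean_ = float(x.mean())
        return self

    def transform(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.clip(np.asarray(x, dtype=float), self.lo_, self.hi_)
        b = BSpline.design_matrix(x, self.knots_, self.degree).toarray()
        fixed = (x - self.x_mean_)[:, None]
        return fixed, b @ self.wiggle_


@dataclass
class TensorSpline2D:
    """Tensor-product smooth of two covariates, decomposed into
    independent variance components the way t2-style tensor smooths are
    built for mixed-model estimation: with marginal bases split into
    null space [1, x] and penalized wiggle Z, the interaction space
    factors into

        fixed (bilinear): {a, b, ab}  (centered; 1 is the intercept)
        Za x {1, b}   -- penalized component 1
        {1, a} x Zb   -- penalized component 2
        Za x Zb       -- penalized component 3

    each penalized component carrying its own smoothing parameter.
    """

    ka: int = 5
    kb: int = 5
    degree: int = 3
    _ma: PSpline1D | None = None
    _mb: PSpline1D | None = None
    means_: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def fit(self, a: np.ndarray, b: np.ndarray) -> "TensorSpline2D":
        self._ma = PSpline1D(k=self.ka, degree=self.degree).fit(a)
        self._mb = PSpline1D(k=self.kb, degree=self.degree).fit(b)
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        self.means_ = (float(a.mean()), float(b.mean()), float((a * b).mean()))
        return self

    def transform(
        self, a: np.ndarray, b: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        fa, za = self._ma.transform(a)
        fb, zb = self._mb.transform(b)
        fixed = np.column_stack(
            [a - self.means_[0], b - self.means_[1], a * b - self.means_[2]]
        )
        z1 = np.hstack([za, za * fb])  # age wiggle x {1, pds}
        z2 = np.hstack([zb, zb * fa])  # {1, age} x pds wiggle
        z3 = za[:, :, None] * zb[:, None, :]
        z3 = z3.reshape(a.size, -1)  # wiggle x wiggle
        return fixed, [z1, z2, z3]


# ---------------------------------------------------------------------------
# the mixed-model solver


@dataclass
class MixedFit:
    """One ML mixed-model fit with the quantities the battery consumes."""

    loglik: float
    sigma2: float
    tau: dict[str, float]
    beta: np.ndarray
    coef: np.ndarray  # all penalized-system coefficients [beta, u_1, ...]
    col_slices: dict[str, slice]  # term/block name -> columns of C
    edf_col: np.ndarray  # per-column effective degrees of freedom
    edf1_col: np.ndarray  # alternative EDF used as smooth-test rank
    total_edf: float
    total_edf1: float
    cov_coef: np.ndarray  # Bayesian covariance of coef
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_obs: int
    design: np.ndarray = field(repr=False, default=None)

    def edf_of(self, names: list[str]) -> float:
        return float(sum(self.edf_col[self.col_slices[n]].sum() for n in names))

    def random_effects(self, name: str) -> np.ndarray:
        return self.coef[self.col_slices[name]]


def _profile_negloglik(logtau, y, x, gs, n):
    tau = np.exp(np.clip(logtau, _LOGTAU_LO, _LOGTAU_HI))
    v = np.eye(n)
    for t, g in zip(tau, gs):
        v += t * g
    try:
        c, low = cho_factor(v, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    vix = cho_solve((c, low), x, check_finite=False)
    viy = cho_solve((c, low), y, check_finite=False)
    xtvx = x.T @ vix
    try:
        beta = np.linalg.solve(xtvx, x.T @ viy)
    except np.linalg.LinAlgError:
        return 1e12
    rss = float(y @ viy - beta @ (x.T @ viy))
    if rss <= 0:
        return 1e12
    sigma2 = rss / n
    return 0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)


def fit_mixed_ml(
    y: np.ndarray,
    x: np.ndarray,
    blocks: dict[str, np.ndarray],
    fixed_names: list[str] | None = None,
) -> MixedFit:
    """ML fit of y = X beta + sum_j Z_j u_j + e.

    ``blocks`` maps block name -> Z_j. Each block gets its own variance
    ratio tau_j, optimized on the log scale (coarse grid start, then
    Nelder-Mead polish of the profiled likelihood).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    n = y.size
    names = list(blocks)
    zs = [np.asarray(blocks[k], dtype=float) for k in names]
    gs = [z @ z.T for z in zs]

    # coarse grid, then local polish
    grid = [-6.0, -2.0, 1.0]
    best, best_val = None, np.inf
    from itertools import product

    for point in product(grid, repeat=len(names)):
        val = _profile_negloglik(np.array(point), y, x, gs, n)
        if val < best_val:
            best, best_val = np.array(point), val
    res = optimize.minimize(
        _profile_negloglik,
        best,
        args=(y, x, gs, n),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000},
    )
    logtau = np.clip(res.x, _LOGTAU_LO, _LOGTAU_HI)
    converged = bool(res.success) and np.isfinite(res.fun) and res.fun < 1e11
    tau = np.exp(logtau)

    # penalized normal equations at the optimum
    c_parts = [x] + zs
    c = np.hstack(c_parts)
    p = x.shape[1]
    pen = np.zeros(c.shape[1])
    col_slices = {"fixed": slice(0, p)}
    at = p
    for name, z, t in zip(names, zs, tau):
        q = z.shape[1]
        col_slices[name] = slice(at, at + q)
        pen[at : at + q] = 1.0 / max(t, math.exp(_LOGTAU_LO))
        at += q
    ctc = c.T @ c
    a = ctc + np.diag(pen)
    a_inv = np.linalg.inv(a)
    coef = a_inv @ (c.T @ y)
    fitted = c @ coef
    resid = y - fitted
    # marginal ML sigma^2 (profiled): recompute from V
    v = np.eye(n)
    for t, g in zip(tau, gs):
        v += t * g
    cf = cho_factor(v, check_finite=False)
    viy = cho_solve(cf, y, check_finite=False)
    vix = cho_solve(cf, x, check_finite=False)
    beta = np.linalg.solve(x.T @ vix, x.T @ viy)
    rss = float(y @ viy - beta @ (x.T @ viy))
    sigma2 = rss / n
    loglik = -float(res.fun)
    m = a_inv @ ctc
    edf_col = np.diag(m).copy()
    # alternative per-column EDF (2tr(F) - tr(FF)) used as smooth-test rank;
    # accounts for smoothing-parameter estimation
    edf1_col = 2.0 * edf_col - np.einsum("ij,ji->i", m, m)
    total_edf = float(np.trace(m))
    total_edf1 = float(edf1_col.sum())
    # scale for coefficient covariance: conditional RSS over the residual
    # degrees of freedom n - edf (the convention of reference GAM
    # implementations); less biased than the profiled ML sigma^2
    scale = float(resid @ resid) / max(n - total_edf, 1.0)
    fit = MixedFit(
        loglik=loglik,
        sigma2=sigma2,
        tau={k: float(t) for k, t in zip(names, tau)},
        beta=beta,
        coef=coef,
        col_slices=col_slices,
        edf_col=edf_col,
        edf1_col=edf1_col,
        total_edf=total_edf,
        total_edf1=total_edf1,
        cov_coef=scale * a_inv,
        fitted=fitted,
        residuals=resid,
        converged=converged,
        n_obs=n,
        design=c,
    )
    if fixed_names is not None:
        fit.fixed_names = list(fixed_names)
    return fit


def smooth_term_test(
    fit: MixedFit,
    fixed_cols: list[int],
    block_names: list[str],
) -> dict:
    """Wood-type F test of a smooth term (its unpenalized null-space
    columns plus its penalized blocks).

    The statistic is T = f' V_f^{r-} f with f the term's contribution at
    the observed covariate values, V_f its Bayesian covariance and r the
    term's effective degrees of freedom; the rank-r pseudoinverse handles
    fractional r by down-weighting the (floor(r)+1)-th eigendirection.
    T/r is referred to F(r, n - total EDF).
    """
    cols = list(fixed_cols)
    for name in block_names:
        sl = fit.col_slices[name]
        cols.extend(range(sl.start, sl.stop))
    cols = np.asarray(cols, dtype=int)
    c_term = fit.design[:, cols]
    theta = fit.coef[cols]
    f_hat = c_term @ theta
    v_theta = fit.cov_coef[np.ix_(cols, cols)]
    edf = max(float(fit.edf_col[cols].sum()), 1.0)
    rank = max(float(fit.edf1_col[cols].sum()), edf)
    rank = min(rank, float(cols.size))

    # eigenstructure of V_f = C_t V_theta C_t' via the small m x m problem
    lam_t, u_t = eigh(v_theta)
    lam_t = np.clip(lam_t, 0.0, None)
    q = c_term @ (u_t * np.sqrt(lam_t))
    # V_f = Q Q'; svd of Q gives eigenpairs of V_f
    uu, ss, _ = np.linalg.svd(q, full_matrices=False)
    lam_f = ss ** 2
    keep = lam_f > (lam_f[0] if lam_f.size else 0.0) * 1e-10
    uu, lam_f = uu[:, keep], lam_f[keep]
    proj = uu.T @ f_hat

    k = int(math.floor(rank))
    nu = rank - k
    k = min(k, lam_f.size)
    t_stat = float(np.sum(proj[:k] ** 2 / lam_f[:k]))
    if nu > 1e-3 and k < lam_f.size:
        t_stat += nu * float(proj[k] ** 2 / lam_f[k])
    df2 = max(fit.n_obs - fit.total_edf, 1.0)
    f_val = t_stat / rank
    p_val = float(f_dist.sf(f_val, rank, df2))
    return {"edf": edf, "F": f_val, "p": p_val, "df2": df2, "rank": rank}


def linear_term_test(fit: MixedFit, fixed_cols: list[int]) -> dict:
    """Wald F test of a set of unpenalized fixed-effect columns."""
    cols = np.asarray(fixed_cols, dtype=int)
    theta = fit.coef[cols]
    v = fit.cov_coef[np.ix_(cols, cols)]
    q = cols.size
    try:
        stat = float(theta @ np.linalg.solve(v, theta)) / q
    except np.linalg.LinAlgError:
        stat = float(theta @ np.linalg.pinv(v) @ theta) / q
    df2 = max(fit.n_obs - fit.total_edf, 1.0)
    return {"edf": float(q), "F": stat, "p": float(f_dist.sf(stat, q, df2)), "df2": df2}


def intercept_with_subject_re(
    y_matrix: np.ndarray, subject_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed intercept and its SE for each column of ``y_matrix`` under an
    intercept + subject-random-intercept model (ML), sharing one
    eigendecomposition of the grouping structure across columns.

    Falls back to mean +/- SEM when only one subject is present.
    """
    y_matrix = np.asarray(y_matrix, dtype=float)
    n = y_matrix.shape[0]
    subjects, inv = np.unique(np.asarray(subject_ids), return_inverse=True)
    if subjects.size < 2:
        logger.info("single subject: intercept curve falls back to mean +/- SEM")
        mu = y_matrix.mean(axis=0)
        se = y_matrix.std(axis=0, ddof=1) / math.sqrt(n)
        return mu, se
    z = np.zeros((n, subjects.size))
    z[np.arange(n), inv] = 1.0
    lam, u = eigh(z @ z.T)
    ones_t = u.T @ np.ones(n)
    y_t = u.T @ y_matrix

    mus = np.empty(y_matrix.shape[1])
    ses = np.empty(y_matrix.shape[1])
    for j in range(y_matrix.shape[1]):
        yj = y_t[:, j]

        def nll(logtau):
            w = 1.0 + math.exp(min(logtau, _LOGTAU_HI)) * lam
            xtvx = float(np.sum(ones_t ** 2 / w))
            xtvy = float(np.sum(ones_t * yj / w))
            mu = xtvy / xtvx
            rss = float(np.sum((yj - mu * ones_t) ** 2 / w))
            if rss <= 0:
                return 1e12
            sigma2 = rss / n
            return 0.5 * (n * math.log(2 * math.pi * sigma2) + np.log(w).sum() + n)

        res = optimize.minimize_scalar(
            nll, bounds=(_LOGTAU_LO, _LOGTAU_HI), method="bounded"
        )
        w = 1.0 + math.exp(res.x) * lam
        xtvx = float(np.sum(ones_t ** 2 / w))
        xtvy = float(np.sum(ones_t * yj / w))
        mu = xtvy / xtvx
        rss = float(np.sum((yj - mu * ones_t) ** 2 / w))
        sigma2 = rss / n
        mus[j] = mu
        ses[j] = math.sqrt(sigma2 / xtvx)
    return mus, ses
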