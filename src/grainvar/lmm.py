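"""Single-variance-component linear mixed models via profiled REML.

The whole package rests on models of the form

    y = X b + u + e,    u ~ N(0, s2_u * A),    e ~ N(0, s2_e * I)

with one structured random term (a sub-block incidence product Z Z', or a
genomic relationship matrix K).  Writing lam = s2_u / s2_e, the covariance is
V = s2_e (I + lam A).  An eigen-decomposition A = U D U' turns every GLS solve
into a diagonally weighted least squares in the rotated basis, so the REML
log-likelihood can be profiled over the single ratio lam and maximised by a
bounded 1-D search.  The same rotation is reused marker-by-marker in the
association scan (EMMAX/P3D style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["EigenA", "RemlFit", "eigen_a", "reml_fit", "NonEstimableError"]

# lam is searched on a log10 grid bracket; wide enough that the boundary
# cases (no random variance / no residual variance) are represented.
_LOG10_LAM_LO = -8.0
_LOG10_LAM_HI = 8.0
_TINY = 1e-300


class NonEstimableError(ValueError):
    """Fixed-effect design is rank deficient (aliased factor levels)."""


@dataclass
class EigenA:
    """Eigen-decomposition of the random-term structure matrix A."""

    values: np.ndarray   # (n,) eigenvalues, >= 0 up to round-off
    vectors: np.ndarray  # (n, n) orthonormal columns

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def rotate(self, m: np.ndarray) -> np.ndarray:
        return self.vectors.T @ m


@dataclass
class RemlFit:
    lam: float                 # s2_u / s2_e at the REML optimum
    beta: np.ndarray           # GLS fixed-effect estimates
    cov_beta: np.ndarray       # s2_e * (X' W X)^-1 in the rotated basis
    sigma2_e: float
    sigma2_u: float
    loglik: float              # REML log-likelihood (up to a constant)
    n_iter: int
    converged: bool
    eig: EigenA = field(repr=False, default=None)
    _resid_rot: np.ndarray = field(repr=False, default=None)

    def blup_u(self) -> np.ndarray:
        """BLUP of the per-observation random effect u = E[u | y]."""
        d = self.eig.values
        w = 1.0 / (1.0 + self.lam * d)
        return self.eig.vectors @ (self.lam * d * w * self._resid_rot)


def eigen_a(a: np.ndarray, jitter: float = 0.0) -> EigenA:
    """Symmetric eigen-decomposition of A (optionally jittered on the diagonal)."""
    a = np.asarray(a, dtype=float)
    if jitter:
        a = a + jitter * np.eye(a.shape[0])
    vals, vecs = np.linalg.eigh(a)
    vals = np.clip(vals, 0.0, None)
    return EigenA(values=vals, vectors=vecs)


def _check_rank(x: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise NonEstimableError(
            f"fixed-effect design has rank {rank} < {x.shape[1]} columns; "
            "some factor levels are aliased"
        )


def _neg_reml(log10_lam: float, d: np.ndarray, yr: np.ndarray, xr: np.ndarray):
    """Negative profiled REML log-likelihood at lam = 10**log10_lam."""
    lam = 10.0 ** log10_lam
    n, p = xr.shape
    w = 1.0 / (1.0 + lam * d)
    sw = np.sqrt(w)
    xw = xr * sw[:, None]
    yw = yr * sw
    xtx = xw.T @ xw
    xty = xw.T @ yw
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        return np.inf, None
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = max(rss / df, _TINY)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf, None
    ll = -0.5 * (np.sum(np.log1p(lam * d)) + df * np.log(sigma2) + logdet_xtx + df)
    return -ll, (lam, beta, xtx, sigma2, rss)


def reml_fit(
    y: np.ndarray,
    x: np.ndarray,
    eig: EigenA,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RemlFit:
    """Fit y = X b + u + e with u ~ N(0, s2_u A) by profiled REML over lam.

    ``eig`` is the eigen-decomposition of A.  The optimiser is a bounded
    Brent search on log10(lam); the boundary lam -> 0 (no random variance)
    is checked explicitly so null heritabilities are reachable exactly.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("y and X have mismatched rows")
    if y.shape[0] != eig.n:
        raise ValueError("eigendecomposition size does not match data")
    _check_rank(x)

    d = eig.values
    yr = eig.rotate(y)
    xr = eig.rotate(x)

    res = minimize_scalar(
        lambda t: _neg_reml(t, d, yr, xr)[0],
        bounds=(_LOG10_LAM_LO, _LOG10_LAM_HI),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    # explicit boundary candidate: lam at the lower bracket == effectively 0
    cand = [res.x, _LOG10_LAM_LO]
    best = min(cand, key=lambda t: _neg_reml(t, d, yr, xr)[0])
    nll, aux = _neg_reml(best, d, yr, xr)
    lam, beta, xtx, sigma2, _rss = aux
    if best == _LOG10_LAM_LO:
        lam = 0.0  # report the boundary as exactly zero random variance
        w = np.ones_like(d)
        xw = xr
        xtx = xw.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ yr)
        resid = yr - xw @ beta
        sigma2 = max(float(resid @ resid) / (len(yr) - x.shape[1]), _TINY)
    cov_beta = sigma2 * np.linalg.inv(xtx)
    resid_rot = yr - xr @ beta
    return RemlFit(
        lam=float(lam),
        beta=beta,
        cov_beta=cov_beta,
        sigma2_e=float(sigma2),
        sigma2_u=float(lam * sigma2),
        loglik=-float(nll),
        n_iter=int(getattr(res, "nfev", 0)),
        converged=bool(res.success),
        eig=eig,
        _resid_rot=resid_rot,
    )
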