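"""Satorra-Bentler mean-scaled test statistic.

Robust ML in covariance modelling keeps the normal-theory point estimates
but rescales the chi-square statistic by a correction factor built from the
empirical fourth moments of the raw data:

    c = tr(U Gamma) / df,     T_sb = T / c,

where Gamma is the asymptotic covariance matrix of the unique elements of S
estimated distribution-free, and U is the normal-theory residual weight
matrix projected off the model tangent space.
"""

from __future__ import annotations

import warnings

import numpy as np

from .fit import FitResult, implied_sigma
from .model import CovModelSpec

__all__ = ["duplication_matrix", "gamma_adf", "sb_scale"]


def duplication_matrix(p: int) -> np.ndarray:
    """D_p with vec(A) = D_p vech(A) for symmetric A (p^2 x p(p+1)/2)."""
    ps = p * (p + 1) // 2
    D = np.zeros((p * p, ps))
    col = 0
    for j in range(p):
        for i in range(j, p):
            D[i * p + j, col] = 1.0
            D[j * p + i, col] = 1.0
            col += 1
    return D


def _vech_indices(p):
    return [(i, j) for j in range(p) for i in range(j, p)]


def gamma_adf(X: np.ndarray) -> np.ndarray:
    """Distribution-free estimate of Acov(sqrt(n) vech(S)) from raw data."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Z = X - X.mean(axis=0)
    idx = _vech_indices(p)
    Y = np.column_stack([Z[:, i] * Z[:, j] for i, j in idx])
    Yc = Y - Y.mean(axis=0)
    return (Yc.T @ Yc) / n


def _delta_matrix(spec: CovModelSpec, theta_hat, eps=1e-6):
    """Jacobian of vech(Sigma) with respect to the free parameters."""
    p = spec.p
    idx = _vech_indices(p)
    q = theta_hat.size
    Delta = np.zeros((len(idx), q))
    for k in range(q):
        th_hi = theta_hat.copy(); th_hi[k] += eps
        th_lo = theta_hat.copy(); th_lo[k] -= eps
        S_hi, _ = implied_sigma(spec, th_hi)
        S_lo, _ = implied_sigma(spec, th_lo)
        d = (S_hi - S_lo) / (2 * eps)
        Delta[:, k] = [d[i, j] for i, j in idx]
    return Delta


def sb_scale(X: np.ndarray, fit: FitResult) -> tuple[float, float]:
    """Compute the Satorra-Bentler scaling factor and scaled statistic.

    Parameters
    ----------
    X : (n, p) raw data matrix from which ``fit.S`` was computed.
    fit : converged ML fit.

    Returns
    -------
    (c, T_sb); also stored on ``fit``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if fit.df == 0:
        fit.sb_scaling_c, fit.T_sb = 1.0, fit.T
        return 1.0, fit.T
    if n < 5 * p:
        warnings.warn(f"n = {n} < 5p = {5 * p}: fourth-moment estimate of "
                      "Gamma may be unstable", stacklevel=2)
    Sigma_inv = np.linalg.inv(fit.sigma_hat)
    D = duplication_matrix(p)
    V = 0.5 * D.T @ np.kron(Sigma_inv, Sigma_inv) @ D
    Delta = _delta_matrix(fit.spec, fit.theta_hat)
    A = Delta.T @ V @ Delta
    U = V - V @ Delta @ np.linalg.solve(A, Delta.T @ V)
    Gamma = gamma_adf(X)
    c = float(np.trace(U @ Gamma) / fit.df)
    T_sb = float(fit.T / c)
    fit.sb_scaling_c, fit.T_sb = c, T_sb
    return c, T_sb
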