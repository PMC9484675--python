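"""Composite reliability (McDonald's omega) and factor scores."""

from __future__ import annotations

import numpy as np

from .fit import FitResult, SemError

__all__ = ["omega", "omega_all", "factor_scores"]


def omega(fit: FitResult, factor: int | str) -> float:
    """McDonald's omega for one factor of a fitted model.

    Share of the variance of the unit-weight composite of the factor's
    indicators that is attributable to the factor:

        omega_f = (1' Lambda_f)^2 phi_f / (1' Sigma_hat 1),

    with the sums restricted to the indicators loading on factor f.  For a
    one-factor congeneric model with standardized indicators this reduces to
    the textbook (sum lambda)^2 / [(sum lambda)^2 + sum theta_ii] form.
    """
    if not fit.converged:
        raise SemError("omega requires a converged fit")
    if isinstance(factor, str):
        factor = fit.spec.factor_names.index(factor)
    L, P, T, B, Phi = fit.matrices()
    mask = L[:, factor] != 0
    if not mask.any():
        return 0.0
    lam = L[mask, factor]
    total = float(np.ones(mask.sum()) @ fit.sigma_hat[np.ix_(mask, mask)]
                  @ np.ones(mask.sum()))
    return float(lam.sum() ** 2 * Phi[factor, factor] / total)


def omega_all(fit: FitResult) -> dict[str, float]:
    return {name: omega(fit, i) for i, name in enumerate(fit.spec.factor_names)}


def factor_scores(fit: FitResult, X: np.ndarray, method: str = "regression"
                  ) -> np.ndarray:
    """Per-subject latent scores.

    ``regression`` (Thomson): scores = Phi Lambda' Sigma^{-1} (x - mean);
    ``bartlett``: (Lambda' Theta^{-1} Lambda)^{-1} Lambda' Theta^{-1} (x - mean).
    """
    if not fit.converged:
        raise SemError("factor scores require a converged fit")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != fit.spec.p:
        raise SemError("data have wrong number of columns")
    Z = X - X.mean(axis=0)
    L, P, T, B, Phi = fit.matrices()
    if method == "regression":
        if np.linalg.cond(fit.sigma_hat) > 1e12:
            raise SemError("implied covariance (near) singular")
        W = Phi @ L.T @ np.linalg.inv(fit.sigma_hat)
    elif method == "bartlett":
        Tinv = np.linalg.inv(T)
        W = np.linalg.solve(L.T @ Tinv @ L, L.T @ Tinv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Z @ W.T
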