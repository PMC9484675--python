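"""Modification indices: univariate score (Lagrange-multiplier) tests.

For a fixed parameter c held at its specified value, the modification index
approximates the drop in the chi-square statistic T if c alone were freed:

    MI = 0.5 * g_c^2 * [H^{-1}]_cc,

where g and H are the gradient and Hessian of T over (free parameters, c)
at the ML solution (the gradient is zero in the free directions).
"""

from __future__ import annotations

import numpy as np

from .fit import FitResult, SemError, _objective_and_grad
from .model import CovModelSpec

__all__ = ["mod_indices"]


def _candidate_specs(spec: CovModelSpec):
    """Fixed residual and latent covariances that could be freed."""
    cands = []
    for i in range(spec.p):
        for j in range(i):
            if not spec.theta.free[i, j]:
                cands.append(("theta", i, j,
                              f"theta[{spec.var_names[i]},{spec.var_names[j]}]"))
    for i in range(spec.m):
        for j in range(i):
            if not spec.psi.free[i, j]:
                cands.append(("psi", i, j,
                              f"psi[{spec.factor_names[i]},{spec.factor_names[j]}]"))
    return cands


def _freed(spec: CovModelSpec, kind, i, j):
    ext = spec.copy()
    mat = ext.theta if kind == "theta" else ext.psi
    mat.set_free(i, j, start=mat.values[i, j])
    return ext


def mod_indices(fit: FitResult, *, h: float = 1e-5) -> dict[str, float]:
    """Modification index for every fixed residual/latent covariance."""
    if not fit.converged:
        raise SemError("modification indices require a converged fit")
    if fit.df < 1:
        raise SemError("saturated model: no restriction to test")
    spec, S, n = fit.spec, fit.S, fit.n
    logdet_S = np.linalg.slogdet(S)[1]
    out = {}
    for kind, i, j, label in _candidate_specs(spec):
        ext = _freed(spec, kind, i, j)
        # extended parameter vector: free params at the optimum, candidate last
        order = ext.param_labels()
        base = fit.estimates
        fixed_val = (spec.theta if kind == "theta" else spec.psi).values[i, j]
        th = np.array([base.get(lab, fixed_val) for lab in order])
        c_idx = order.index(label)

        def grad(v):
            return _objective_and_grad(ext, v, S, logdet_S)[1]

        g = grad(th) * (n - 1)
        q = th.size
        H = np.zeros((q, q))
        for k in range(q):
            hi = th.copy(); hi[k] += h
            lo = th.copy(); lo[k] -= h
            H[:, k] = (grad(hi) - grad(lo)) / (2 * h) * (n - 1)
        H = 0.5 * (H + H.T)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            out[label] = np.nan
            continue
        if Hinv[c_idx, c_idx] <= 0:
            out[label] = np.nan
            continue
        out[label] = float(0.5 * g[c_idx] ** 2 * Hinv[c_idx, c_idx])
    return out
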