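"""Maximum-likelihood fitting of structured covariance models.

The discrepancy minimized is the normal-theory ML fit function

    F_ML(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^{-1}) - p,

with analytic gradient, quasi-Newton (L-BFGS-B) optimization under box
constraints, and jittered multi-start on non-convergence.  The test
statistic is T = (n-1) F_ML at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import CovModelSpec

__all__ = ["FitResult", "fit_ml", "fit_indices", "baseline_independence",
           "implied_sigma", "latent_regression", "SemError"]


class SemError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _unpack(spec: CovModelSpec, theta: np.ndarray):
    """Return (Lambda, Psi, Theta, B) matrices for a parameter vector."""
    L = spec.loadings.values.copy()
    P = spec.psi.values.copy()
    T = spec.theta.values.copy()
    B = spec.beta.values.copy()
    k = 0
    for i, j in spec.loadings.free_indices():
        L[i, j] = theta[k]; k += 1
    for i, j in spec.psi.free_indices():
        P[i, j] = P[j, i] = theta[k]; k += 1
    for i, j in spec.theta.free_indices():
        T[i, j] = T[j, i] = theta[k]; k += 1
    for i, j in spec.beta.free_indices():
        B[i, j] = theta[k]; k += 1
    return L, P, T, B


def implied_sigma(spec: CovModelSpec, theta: np.ndarray):
    """Model-implied covariance matrix Sigma(theta) and intermediates."""
    L, P, T, B = _unpack(spec, theta)
    m = spec.m
    M = np.linalg.solve(np.eye(m) - B, np.eye(m))
    Phi = M @ P @ M.T
    Sigma = L @ Phi @ L.T + T
    return Sigma, (L, P, T, B, M, Phi)


def _objective_and_grad(spec: CovModelSpec, theta, S, logdet_S):
    Sigma, (L, P, T, B, M, Phi) = implied_sigma(spec, theta)
    p = spec.p
    try:  # Cholesky doubles as the positive-definiteness check
        C = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    logdet = 2.0 * float(np.sum(np.log(np.diag(C))))
    if not np.isfinite(logdet):
        return 1e10, np.zeros_like(theta)
    Ci = np.linalg.inv(C)
    Sinv = Ci.T @ Ci
    F = logdet - logdet_S + float(np.sum(Sinv * S)) - p
    # gradient: dF = tr(E dSigma), E = Sigma^-1 - Sigma^-1 S Sigma^-1
    E = Sinv - Sinv @ S @ Sinv
    W = L @ M
    GL = 2.0 * E @ L @ Phi
    GP = W.T @ E @ W
    GB = 2.0 * (M @ P @ W.T @ E @ L @ M).T
    grad = []
    for i, j in spec.loadings.free_indices():
        grad.append(GL[i, j])
    for i, j in spec.psi.free_indices():
        grad.append(GP[i, j] if i == j else 2.0 * GP[i, j])
    for i, j in spec.theta.free_indices():
        grad.append(E[i, j] if i == j else 2.0 * E[i, j])
    for i, j in spec.beta.free_indices():
        grad.append(GB[i, j])
    return F, np.asarray(grad)


def _start_values(spec: CovModelSpec, S):
    """Fill NaN start values with data-informed defaults."""
    s_diag = np.diag(S)
    mean_var = float(np.mean(s_diag))
    theta0 = []
    for i, j in spec.loadings.free_indices():
        v = spec.loadings.values[i, j]
        theta0.append(v if np.isfinite(v) else 0.7 * np.sqrt(s_diag[i]))
    for i, j in spec.psi.free_indices():
        v = spec.psi.values[i, j]
        if np.isfinite(v):
            theta0.append(v)
        else:
            theta0.append(0.5 * mean_var if i == j else 0.0)
    for i, j in spec.theta.free_indices():
        v = spec.theta.values[i, j]
        if np.isfinite(v):
            theta0.append(v)
        else:
            theta0.append(0.5 * s_diag[i] if i == j else 0.0)
    for i, j in spec.beta.free_indices():
        v = spec.beta.values[i, j]
        theta0.append(v if np.isfinite(v) else 0.0)
    return np.asarray(theta0)


def _bounds(spec: CovModelSpec):
    lab = spec.param_labels()
    return [spec.bounds.get(name, (-np.inf, np.inf)) for name in lab]


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    spec: CovModelSpec
    theta_hat: np.ndarray
    param_labels: list[str]
    sigma_hat: np.ndarray
    f_ml: float
    T: float
    df: int
    p_value: float
    n: int
    S: np.ndarray
    cfi: float
    rmsea: float
    srmr: float
    aic: float
    baseline_T: float
    baseline_df: int
    converged: bool
    grad_norm: float
    standardized: dict = field(default_factory=dict)
    r_squared: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    sb_scaling_c: float | None = None
    T_sb: float | None = None

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_labels, self.theta_hat))

    def matrices(self):
        """(Lambda, Psi, Theta, B, Phi) at the ML solution."""
        _, (L, P, T, B, M, Phi) = implied_sigma(self.spec, self.theta_hat)
        return L, P, T, B, Phi

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.name,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "f_ml": float(self.f_ml),
            "chi_square": float(self.T),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "cfi": float(self.cfi),
            "rmsea": float(self.rmsea),
            "srmr": float(self.srmr),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "warnings": list(self.warnings),
            "standardized": {k: np.asarray(v).tolist()
                             for k, v in self.standardized.items()},
            "r_squared": {k: float(v) for k, v in self.r_squared.items()},
        }
        if self.sb_scaling_c is not None:
            d["sb_scaling_c"] = float(self.sb_scaling_c)
            d["chi_square_sb"] = float(self.T_sb)
        return d


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def baseline_independence(S, n):
    """Independence baseline (diagonal Sigma, free variances): closed form.

    The MLE is Sigma = diag(S), giving F = -ln|R| with R the correlation
    matrix of S.
    """
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    F_b = -logdet
    p = S.shape[0]
    return (n - 1) * F_b, p * (p - 1) // 2


def fit_indices(T, df, T_b, df_b, n, S, sigma_hat, q):
    """CFI, RMSEA, SRMR and AIC from the fitted and baseline statistics."""
    if df == 0:
        cfi, rmsea = 1.0, 0.0
    else:
        num = max(T - df, 0.0)
        den = max(T_b - df_b, T - df, 0.0)
        cfi = 1.0 - (num / den if den > 0 else 0.0)
        rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
    d = np.sqrt(np.diag(S))
    res = (S - sigma_hat) / np.outer(d, d)
    iu = np.triu_indices_from(res)
    srmr = float(np.sqrt(np.mean(res[iu] ** 2)))
    # -2 loglik up to an additive data constant; only AIC differences matter
    Sinv_term = float(np.sum(np.linalg.inv(sigma_hat) * S))
    m2ll = (n - 1) * (np.linalg.slogdet(sigma_hat)[1] + Sinv_term)
    aic = float(m2ll + 2 * q)
    return float(cfi), float(rmsea), srmr, aic


def fit_ml(spec: CovModelSpec, S, n: int, *, n_starts: int = 1,
           max_extra_starts: int = 5, gtol: float = 1e-8,
           seed: int = 0) -> FitResult:
    """Fit a structured covariance model by maximum likelihood.

    Parameters
    ----------
    spec : CovModelSpec
    S : (p, p) sample covariance (or correlation) matrix, symmetric PD.
    n : number of observations behind S.
    n_starts : initial number of optimizer starts (first from the pattern
        start values, remainder jittered).
    max_extra_starts : additional jittered starts tried if the gradient norm
        at the best solution is still poor.
    """
    S = np.asarray(S, dtype=float)
    spec.check_identification()
    p = spec.p
    if S.shape != (p, p):
        raise SemError(f"S has shape {S.shape}, expected ({p}, {p})")
    if not np.allclose(S, S.T, atol=1e-10):
        raise SemError("S is not symmetric")
    evals = np.linalg.eigvalsh(S)
    warns = []
    if evals.min() <= 0:
        raise SemError("S is not positive definite")
    if n <= p:
        warns.append(f"n = {n} not larger than p = {p}; statistics unreliable")
    logdet_S = np.linalg.slogdet(S)[1]

    fun = lambda th: _objective_and_grad(spec, th, S, logdet_S)
    theta0 = _start_values(spec, S)
    bounds = _bounds(spec)
    rng = np.random.default_rng(seed)

    best_x, best_f, best_dec = None, np.inf, np.inf
    tries = 0
    while True:
        start = theta0 if tries == 0 else theta0 * (1 + 0.3 * rng.standard_normal(theta0.size)) + 0.05 * rng.standard_normal(theta0.size)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(fun, start, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-12})
        x, f, dec = _newton_polish(fun, res.x, bounds)
        if f < best_f - 1e-12 or (abs(f - best_f) <= 1e-12 and dec < best_dec):
            best_x, best_f, best_dec = x, f, dec
        tries += 1
        if best_dec < max(gtol, 1e-10) or tries >= n_starts + max_extra_starts:
            break

    theta_hat = best_x
    F = float(best_f)
    if F >= 1e9:
        raise SemError(f"model '{spec.name}' did not converge "
                       f"(implied covariance not positive definite)")
    gn = _free_grad_norm(fun, theta_hat, bounds)
    # decrement of 1e-5 in F corresponds to a vanishing change in T
    converged = best_dec < 1e-5 or gn < 1e-6
    if not converged:
        warns.append(f"Newton decrement {best_dec:.2e} at solution; "
                     "treat with caution")

    Sigma, (L, P, T_m, B, M, Phi) = implied_sigma(spec, theta_hat)
    # Heywood diagnostics
    labels = spec.param_labels()
    for lab, val in zip(labels, theta_hat):
        if lab.startswith(("theta[", "psi[")) and _is_diag_label(lab) and val < 0:
            warns.append(f"Heywood case: {lab} = {val:.4g} < 0; "
                         "consider a lower bound of ~1e-6")
    Tstat = (n - 1) * F
    df = spec.df()
    p_value = float(stats.chi2.sf(Tstat, df)) if df > 0 else 1.0
    T_b, df_b = baseline_independence(S, n)
    cfi, rmsea, srmr, aic = fit_indices(Tstat, df, T_b, df_b, n, S, Sigma,
                                        spec.n_free)

    std, r2 = _standardize(spec, L, P, T_m, B, Phi, Sigma)
    return FitResult(spec=spec, theta_hat=theta_hat, param_labels=labels,
                     sigma_hat=Sigma, f_ml=F, T=float(Tstat), df=df,
                     p_value=p_value, n=n, S=S, cfi=cfi, rmsea=rmsea,
                     srmr=srmr, aic=aic, baseline_T=float(T_b),
                     baseline_df=df_b, converged=converged, grad_norm=gn,
                     standardized=std, r_squared=r2, warnings=warns)


def _active_bound_mask(x, g, bounds, tol=1e-9):
    """Coordinates pinned at a bound with the gradient pushing outward."""
    mask = np.zeros(x.size, dtype=bool)
    for k, (lo, hi) in enumerate(bounds):
        if lo > -np.inf and x[k] - lo <= tol and g[k] > 0:
            mask[k] = True
        elif hi < np.inf and hi - x[k] <= tol and g[k] < 0:
            mask[k] = True
    return mask


def _free_grad_norm(fun, x, bounds):
    g = fun(x)[1]
    g = g.copy()
    g[_active_bound_mask(x, g, bounds)] = 0.0
    return float(np.linalg.norm(g))


def _newton_polish(fun, x, bounds, max_iter=15, h=1e-6):
    """Damped Newton refinement with a numeric Hessian of the analytic
    gradient.  Handles active box constraints by freezing those
    coordinates.  Returns (x, F, Newton decrement)."""
    x = x.copy()
    q = x.size
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    F, g = fun(x)
    dec = np.inf
    for _ in range(max_iter):
        free = ~_active_bound_mask(x, g, bounds)
        if not free.any():
            dec = 0.0
            break
        idx = np.flatnonzero(free)
        H = np.zeros((idx.size, idx.size))
        for a, k in enumerate(idx):
            xp = x.copy(); xp[k] += h
            xm = x.copy(); xm[k] -= h
            H[a] = (fun(xp)[1][idx] - fun(xm)[1][idx]) / (2 * h)
        H = 0.5 * (H + H.T)
        gf = g[idx]
        try:
            w, V = np.linalg.eigh(H)
        except np.linalg.LinAlgError:
            break
        w_reg = np.maximum(np.abs(w), 1e-10 * max(np.abs(w).max(), 1.0))
        step = -V @ ((V.T @ gf) / w_reg)
        dec = float(0.5 * gf @ (V @ ((V.T @ gf) / w_reg)))
        if dec < 1e-14:
            break
        # backtracking line search within the box
        t = 1.0
        improved = False
        for _ls in range(30):
            x_new = x.copy()
            x_new[idx] = np.clip(x[idx] + t * step, lo[idx], hi[idx])
            F_new, g_new = fun(x_new)
            if F_new < F - 1e-16:
                x, F, g = x_new, F_new, g_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return x, float(F), float(dec)


def _is_diag_label(lab):
    inner = lab[lab.index("[") + 1:-1]
    a, b = inner.split(",")
    return a == b


def _standardize(spec, L, P, T, B, Phi, Sigma):
    """Standardized solution: unit-variance observed and latent variables."""
    sd_obs = np.sqrt(np.diag(Sigma))
    sd_lat = np.sqrt(np.clip(np.diag(Phi), 1e-300, None))
    lam_std = L * sd_lat[None, :] / sd_obs[:, None]
    theta_std = T / np.outer(sd_obs, sd_obs)
    phi_std = Phi / np.outer(sd_lat, sd_lat)
    beta_std = B * sd_lat[None, :] / sd_lat[:, None]
    psi_std = P / np.outer(sd_lat, sd_lat)
    r2 = {}
    for k in spec.endogenous():
        r2[spec.factor_names[k]] = float(1.0 - P[k, k] / Phi[k, k])
    std = {"lambda": lam_std, "theta": theta_std, "phi": phi_std,
           "beta": beta_std, "psi": psi_std}
    return std, r2


def latent_regression(spec: CovModelSpec, S, n: int, **kw) -> FitResult:
    """Fit a model containing structural paths among latents.

    Thin wrapper over :func:`fit_ml` that insists the model actually has an
    endogenous latent and reports standardized paths and R-squared.
    """
    if not spec.endogenous():
        raise SemError("spec declares no structural paths (beta all zero)")
    spec.check_identification()
    return fit_ml(spec, S, n, **kw)
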