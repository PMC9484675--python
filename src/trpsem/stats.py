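"""Descriptive and inferential statistics, implemented from formulas.

Covers the descriptive table (mean, SD, min, max, adjusted skewness and
excess kurtosis), Pearson correlations with exact t-test p values and
Fisher-z 95% confidence intervals, a one-way repeated-measures ANOVA with
Mauchly's sphericity test, Greenhouse-Geisser correction, three eta-squared
variants and Bonferroni pairwise t tests, and the upper-median subsample
correlation used in range-restriction reanalyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["describe", "describe_table", "pearson", "corr_matrix",
           "rm_anova", "split_half_subsample_corr", "CorrResult",
           "AnovaResult"]


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def describe(values) -> dict:
    """Sample moments: SD with n-1, adjusted (SPSS-style) skewness G1 and
    excess kurtosis G2 (normal -> 0).  Constant input flags skewness and
    kurtosis as undefined (NaN)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("describe needs at least 2 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    out = {"n": n, "mean": float(mean), "sd": float(sd),
           "min": float(x.min()), "max": float(x.max())}
    if sd == 0:
        out.update(skewness=np.nan, kurtosis=np.nan, flags=["constant input"])
        return out
    d = x - mean
    m2 = np.mean(d ** 2)
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    g1 = m3 / m2 ** 1.5
    skew = g1 * np.sqrt(n * (n - 1)) / (n - 2) if n > 2 else np.nan
    if n > 3:
        kurt = ((n + 1) * (n - 1) / ((n - 2) * (n - 3))
                * (m4 / m2 ** 2 - 3.0 * (n - 1) / (n + 1)))
    else:
        kurt = np.nan
    out.update(skewness=float(skew), kurtosis=float(kurt), flags=[])
    return out


def describe_table(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Descriptive table (one row per variable), column order M, SD, Min,
    Max, Skewness, Kurtosis."""
    columns = list(df.columns if columns is None else columns)
    rows = {}
    for c in columns:
        d = describe(df[c].to_numpy())
        rows[c] = [d["mean"], d["sd"], d["min"], d["max"],
                   d["skewness"], d["kurtosis"]]
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["M", "SD", "Min", "Max", "Skewness", "Kurtosis"])


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrResult:
    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    flags: list = field(default_factory=list)


def pearson(x, y, *, conf: float = 0.95) -> CorrResult:
    """Pearson r with two-sided t test and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("pearson needs at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return _corr_from_r(r, n, conf)


def _corr_from_r(r: float, n: int, conf: float = 0.95) -> CorrResult:
    flags = []
    if abs(r) >= 1.0 - 1e-14:
        return CorrResult(r=float(np.sign(r)), n=n, p_value=0.0,
                          ci_low=float(np.sign(r)), ci_high=float(np.sign(r)),
                          flags=["degenerate: |r| = 1"])
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + conf / 2.0)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return CorrResult(r=r, n=n, p_value=float(p), ci_low=float(lo),
                      ci_high=float(hi), flags=flags)


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a reported correlation."""
    res = _corr_from_r(float(r), int(n), conf)
    return res.ci_low, res.ci_high


def corr_matrix(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix (lower layout matches the
    published tables when printed with the same variable order)."""
    columns = list(df.columns if columns is None else columns)
    return df[columns].corr(method="pearson")


__all__.append("fisher_ci")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df1: float
    df2: float
    p_value: float
    p_value_gg: float
    epsilon_gg: float
    mauchly_W: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    eta_sq: float
    eta_sq_partial: float
    eta_sq_generalized: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    pairwise: pd.DataFrame = None


def rm_anova(data) -> AnovaResult:
    """One-way repeated-measures ANOVA on an n x k complete-case matrix.

    Sums of squares by direct decomposition; Greenhouse-Geisser epsilon
    from the double-centered condition covariance; Mauchly's W with its
    chi-square approximation; Bonferroni-adjusted pairwise paired t tests.
    """
    X = np.asarray(data, dtype=float)
    if np.isnan(X).any():
        raise ValueError("complete cases required")
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n <= k:
        raise ValueError("need more subjects than conditions")
    grand = X.mean()
    cond_means = X.mean(axis=0)
    subj_means = X.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    p = float(sps.f.sf(F, df1, df2))

    # Greenhouse-Geisser epsilon from the double-centered covariance
    S = np.cov(X, rowvar=False, ddof=1)
    J = np.eye(k) - np.ones((k, k)) / k
    Cbar = J @ S @ J
    denom = (k - 1) * np.trace(Cbar @ Cbar)
    eps = float(np.trace(Cbar) ** 2 / denom) if denom > 0 else 1.0
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2))

    # Mauchly's test on orthonormal contrasts
    C = _orthonormal_contrasts(k)
    A = C @ S @ C.T
    d = k - 1
    W = float(np.linalg.det(A) / (np.trace(A) / d) ** d)
    f_corr = 1.0 - (2.0 * d ** 2 + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(W) if W > 0 else np.inf
    df_m = d * (d + 1) // 2 - 1
    p_m = float(sps.chi2.sf(chi2, df_m)) if df_m > 0 else 1.0

    eta = ss_cond / ss_tot
    eta_p = ss_cond / (ss_cond + ss_err)
    eta_g = ss_cond / (ss_cond + ss_subj + ss_err)

    m = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        t, pt = sps.ttest_rel(X[:, i], X[:, j])
        rows.append({"a": i, "b": j, "t": float(t), "df": n - 1,
                     "p_raw": float(pt), "p_bonf": float(min(pt * m, 1.0))})
    return AnovaResult(F=float(F), df1=float(eps * df1 if k > 2 else df1),
                       df2=float(eps * df2 if k > 2 else df2),
                       p_value=p, p_value_gg=p_gg, epsilon_gg=eps,
                       mauchly_W=W, mauchly_chi2=float(chi2),
                       mauchly_df=df_m, mauchly_p=p_m,
                       eta_sq=float(eta), eta_sq_partial=float(eta_p),
                       eta_sq_generalized=float(eta_g),
                       ss_condition=float(ss_cond), ss_subject=float(ss_subj),
                       ss_error=float(ss_err), pairwise=pd.DataFrame(rows))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.sqrt(i * (i + 1))
    return H


# ---------------------------------------------------------------------------
# subsample correlation
# ---------------------------------------------------------------------------

def split_half_subsample_corr(df: pd.DataFrame, split_var: str,
                              stat_var1: str, stat_var2: str) -> CorrResult:
    """Pearson correlation within the upper-median half of ``split_var``.

    The upper half is defined as values >= the median; if ties at the
    median push the subsample above half the sample this is flagged."""
    med = df[split_var].median()
    upper = df[df[split_var] >= med]
    res = pearson(upper[stat_var1], upper[stat_var2])
    if len(upper) > (len(df) + 1) // 2:
        res.flags.append(f"ties at median: upper half has {len(upper)} of "
                         f"{len(df)} rows")
    return res
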