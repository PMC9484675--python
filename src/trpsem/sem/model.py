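"""Structured covariance model specification.

A model is written in LISREL/RAM-like form over p observed variables and m
latent variables:

    eta   = B eta + zeta,          zeta ~ (0, Psi)
    x     = Lambda eta + eps,      eps  ~ (0, Theta)

so the implied covariance matrix is

    Sigma(theta) = Lambda (I-B)^{-1} Psi (I-B)^{-T} Lambda' + Theta.

Every entry of Lambda, B, Psi and Theta is either *fixed* at a numeric value
(e.g. the fixed-links loadings 0,1,2,3) or *free* with an optional start
value.  Pure confirmatory factor models set B = 0, in which case Psi is the
latent covariance matrix itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["PatternMatrix", "CovModelSpec", "free_cell", "fixed_cell"]

_FREE = object()


def free_cell(start: float = np.nan):
    """Marker for a freely estimated entry with optional start value."""
    return ("free", float(start))


def fixed_cell(value: float):
    return ("fixed", float(value))


class PatternMatrix:
    """A matrix whose entries are fixed values or free parameters.

    Internally two arrays: ``values`` (fixed value, or start value for free
    entries; NaN start means "choose automatically at fit time") and ``free``
    (boolean mask).  Symmetric pattern matrices keep the mask and values
    symmetric; their free parameters are counted on the lower triangle only.
    """

    def __init__(self, shape, symmetric: bool = False):
        self.values = np.zeros(shape, dtype=float)
        self.free = np.zeros(shape, dtype=bool)
        self.symmetric = bool(symmetric)

    def set_fixed(self, i, j, value):
        self.values[i, j] = value
        self.free[i, j] = False
        if self.symmetric and i != j:
            self.values[j, i] = value
            self.free[j, i] = False

    def set_free(self, i, j, start=np.nan):
        self.values[i, j] = start
        self.free[i, j] = True
        if self.symmetric and i != j:
            self.values[j, i] = start
            self.free[j, i] = True

    def free_indices(self):
        """(i, j) pairs of free parameters (lower triangle if symmetric)."""
        idx = []
        n_i, n_j = self.free.shape
        for i in range(n_i):
            for j in range(n_j):
                if self.free[i, j] and (not self.symmetric or j <= i):
                    idx.append((i, j))
        return idx

    def copy(self):
        out = PatternMatrix(self.free.shape, self.symmetric)
        out.values = self.values.copy()
        out.free = self.free.copy()
        return out

    def to_cells(self):
        out = []
        for i in range(self.values.shape[0]):
            row = []
            for j in range(self.values.shape[1]):
                if self.free[i, j]:
                    s = self.values[i, j]
                    row.append("free" if np.isnan(s) else f"free:{s:g}")
                else:
                    row.append(f"fixed:{self.values[i, j]:g}")
            out.append(row)
        return out

    @classmethod
    def from_cells(cls, cells, symmetric=False):
        arr = np.asarray(cells, dtype=object)
        pm = cls(arr.shape, symmetric=symmetric)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                cell = str(arr[i, j])
                if cell.startswith("free"):
                    start = float(cell.split(":", 1)[1]) if ":" in cell else np.nan
                    pm.set_free(i, j, start)
                else:
                    val = float(cell.split(":", 1)[1]) if ":" in cell else float(cell)
                    pm.set_fixed(i, j, val)
        return pm


@dataclass
class CovModelSpec:
    """Full specification of a structured covariance model."""

    var_names: list[str]
    factor_names: list[str]
    loadings: PatternMatrix  # p x m
    psi: PatternMatrix       # m x m, symmetric (latent/disturbance covariances)
    theta: PatternMatrix     # p x p, symmetric (residual covariances)
    beta: PatternMatrix | None = None  # m x m latent paths; None -> all zero
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self):
        p, m = len(self.var_names), len(self.factor_names)
        if self.loadings.values.shape != (p, m):
            raise ValueError("loading pattern has wrong shape")
        if self.psi.values.shape != (m, m) or self.theta.values.shape != (p, p):
            raise ValueError("psi/theta pattern has wrong shape")
        if self.beta is None:
            self.beta = PatternMatrix((m, m))
        if np.any(np.diag(self.beta.free)) or np.any(np.diag(self.beta.values)):
            raise ValueError("beta diagonal must be fixed at zero")

    @property
    def p(self) -> int:
        return len(self.var_names)

    @property
    def m(self) -> int:
        return len(self.factor_names)

    # --- free-parameter bookkeeping -------------------------------------
    def param_labels(self) -> list[str]:
        labels = []
        v, f = self.var_names, self.factor_names
        for i, j in self.loadings.free_indices():
            labels.append(f"lambda[{v[i]},{f[j]}]")
        for i, j in self.psi.free_indices():
            labels.append(f"psi[{f[i]},{f[j]}]")
        for i, j in self.theta.free_indices():
            labels.append(f"theta[{v[i]},{v[j]}]")
        for i, j in self.beta.free_indices():
            labels.append(f"beta[{f[i]},{f[j]}]")
        return labels

    @property
    def n_free(self) -> int:
        return len(self.param_labels())

    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free

    def check_identification(self):
        if self.n_free > self.p * (self.p + 1) // 2:
            raise ValueError(
                f"model '{self.name}' has {self.n_free} free parameters but only "
                f"{self.p * (self.p + 1) // 2} distinct covariance moments"
            )

    def endogenous(self) -> list[int]:
        """Indices of latents that receive at least one structural path."""
        mask = self.beta.free | (self.beta.values != 0)
        return [i for i in range(self.m) if mask[i].any()]

    def copy(self) -> "CovModelSpec":
        return CovModelSpec(
            var_names=list(self.var_names),
            factor_names=list(self.factor_names),
            loadings=self.loadings.copy(),
            psi=self.psi.copy(),
            theta=self.theta.copy(),
            beta=self.beta.copy(),
            bounds=dict(self.bounds),
            name=self.name,
        )

    # --- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "var_names": list(self.var_names),
            "factor_names": list(self.factor_names),
            "loadings": self.loadings.to_cells(),
            "psi": self.psi.to_cells(),
            "theta": self.theta.to_cells(),
            "beta": self.beta.to_cells(),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovModelSpec":
        return cls(
            var_names=list(d["var_names"]),
            factor_names=list(d["factor_names"]),
            loadings=PatternMatrix.from_cells(d["loadings"]),
            psi=PatternMatrix.from_cells(d["psi"], symmetric=True),
            theta=PatternMatrix.from_cells(d["theta"], symmetric=True),
            beta=PatternMatrix.from_cells(d["beta"]),
            bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
            name=d.get("name", "model"),
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CovModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
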