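"""Populations of simulated observers.

Each observer is a vector of psychophysical parameters derived from four
correlated latent traits:

* ``trp`` — temporal resolution power on a *badness* scale (higher values
  mean poorer timing), so that it loads positively on the four timing-task
  measures and carries a negative structural path to intelligence;
* ``ssc`` — the size-invariant component of the motion-direction duration
  thresholds (constant latent variable, loadings 1,1,1,1 on log10 ms);
* ``ssi`` — the size-increasing component (loadings 0,1,2,3), i.e. genuine
  spatial suppression;
* ``g`` — psychometric intelligence.

The default latent correlation matrix is constructed from the structural
paths of the combined study model (g regressed on trp/ssc/ssi with
standardized coefficients -.535/-.058/-.140, r(trp,ssc)=.353,
r(trp,ssi)=.180, ssc and ssi orthogonal), so a default synthetic study
resembles the published effect sizes.  Task parameters are linear in the
latents on a log10 scale with Gaussian residuals, matching the linear
fixed-links measurement model the analysis is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .adaptive import logistic_2afc, weibull_2afc

__all__ = ["PopulationSpec", "ObserverParams", "default_latent_corr",
           "sample_population", "generate_bis_subtests",
           "population_threshold_cov",
           "respond_motion", "respond_duration_discrimination",
           "respond_generalization", "respond_rhythm",
           "motion_p_correct", "dd_p_correct", "tg_p_yes", "rp_p_correct",
           "W_SIZES", "TG_DURATIONS", "TG_STANDARD"]

#: fixed-links loading weights over the four stimulus sizes
W_SIZES = np.array([0.0, 1.0, 2.0, 3.0])

#: temporal generalization stimulus set (ms) and standard
TG_STANDARD = 75.0
TG_DURATIONS = (42.0, 53.0, 64.0, 75.0, 86.0, 97.0, 108.0)

LATENT_NAMES = ("trp", "ssc", "ssi", "g")
TIMING_TASKS = ("dde", "ddf", "tg", "rp")


def default_latent_corr(beta_trp_g: float = -0.535,
                        beta_ssc_g: float = -0.058,
                        beta_ssi_g: float = -0.140,
                        r_trp_ssc: float = 0.353,
                        r_trp_ssi: float = 0.180) -> np.ndarray:
    """Latent correlation matrix implied by the combined structural model.

    g is a linear function of (trp, ssc, ssi) plus an independent
    disturbance scaled so that var(g) = 1.
    """
    R3 = np.array([[1.0, r_trp_ssc, r_trp_ssi],
                   [r_trp_ssc, 1.0, 0.0],
                   [r_trp_ssi, 0.0, 1.0]])
    b = np.array([beta_trp_g, beta_ssc_g, beta_ssi_g])
    r2 = float(b @ R3 @ b)
    if r2 >= 1.0:
        raise ValueError("structural paths imply R^2 >= 1 for g")
    rg = R3 @ b
    R = np.eye(4)
    R[:3, :3] = R3
    R[3, :3] = R[:3, 3] = rg
    return R


@dataclass
class PopulationSpec:
    """Generative description of a synthetic study population.

    Scales: duration thresholds live on log10 ms; timing-task parameters
    are lognormal (linear in the latents on log10); intelligence composites
    are z-scaled.  Defaults are calibrated to the published group-level
    statistics of the motivating study (mean suppression index .29, latent
    variances .022/.003, timing means/SDs of its descriptive table).
    """
    n_subjects: int = 273
    latent_corr: np.ndarray = field(default_factory=default_latent_corr)
    beta_trp_g: float = -0.535
    # motion thresholds, log10 ms
    base_log_threshold: float = 1.25
    mean_si: float = 0.29
    ssc_sd: float = float(np.sqrt(0.022))
    ssi_sd: float = float(np.sqrt(0.003))
    # timing tasks: base parameter (ms), total log10 SD, TRP loading fraction
    timing_base: dict = field(default_factory=lambda: {
        "dde": 16.3, "ddf": 7.8, "tg": 6.6, "rp": 49.6})
    timing_sd: dict = field(default_factory=lambda: {
        "dde": 0.19, "ddf": 0.16, "tg": 0.18, "rp": 0.17})
    timing_loading: dict = field(default_factory=lambda: {
        "dde": 0.55, "ddf": 0.70, "tg": 0.58, "rp": 0.40})
    # intelligence composites: standardized loadings on g
    bis_loadings: tuple = (0.776, 0.658, 0.593)
    bis_subtest_r: float = 0.9
    # residual SDs of trait-level noise
    noise_sds: dict = field(default_factory=lambda: {"mdd": 0.05})
    # psychometric function family
    psychometric_slope: float = 3.5
    lapse_rate: float = 0.01
    family: str = "weibull"
    seed: int = 12345

    def validate(self) -> None:
        R = np.asarray(self.latent_corr, dtype=float)
        if R.shape != (4, 4):
            raise ValueError("latent_corr must be 4x4 over (trp, ssc, ssi, g)")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("latent_corr must have a unit diagonal")
        ev = np.linalg.eigvalsh(R)
        if ev.min() < -1e-10:
            raise ValueError(
                f"latent_corr is not positive semi-definite "
                f"(smallest eigenvalue {ev.min():.3g})")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        for name, val in [("ssc_sd", self.ssc_sd), ("ssi_sd", self.ssi_sd)]:
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.noise_sds.values()):
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["latent_corr"] = np.asarray(self.latent_corr).tolist()
        d["bis_loadings"] = list(self.bis_loadings)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        if "latent_corr" in d:
            d["latent_corr"] = np.asarray(d["latent_corr"], dtype=float)
        if "bis_loadings" in d:
            d["bis_loadings"] = tuple(d["bis_loadings"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ObserverParams:
    """True psychophysical parameters of one simulated observer."""
    subject: int
    mdd_log_threshold: np.ndarray  # log10 ms at 82% correct, per stimulus size
    dd_jnd_empty: float            # ms
    dd_jnd_filled: float           # ms
    tg_sd: float                   # ms
    rp_jnd: float                  # ms
    psychometric_slope: float = 3.5
    lapse_rate: float = 0.01
    family: str = "weibull"

    def __post_init__(self):
        if not np.all(np.isfinite(self.mdd_log_threshold)):
            raise ValueError("thresholds must be finite")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.psychometric_slope <= 0:
            raise ValueError("slope must be positive")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _corr_factor(R):
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:  # PSD but singular
        w, V = np.linalg.eigh(R)
        return V @ np.diag(np.sqrt(np.clip(w, 0, None)))


def sample_population(spec: PopulationSpec, seed: int | None = None
                      ) -> tuple[list[ObserverParams], pd.DataFrame]:
    """Draw a population of observers; returns (observers, latent table).

    Deterministic given the seed (``spec.seed`` unless overridden).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    Z = rng.standard_normal((n, 4)) @ _corr_factor(np.asarray(
        spec.latent_corr, dtype=float)).T
    latents = pd.DataFrame(Z, columns=list(LATENT_NAMES))
    latents.insert(0, "subject", np.arange(n))

    slope_per_size = spec.mean_si / W_SIZES[-1]
    mdd_noise = spec.noise_sds.get("mdd", 0.0)
    observers = []
    for i in range(n):
        z_trp, z_ssc, z_ssi, _z_g = Z[i]
        eps = rng.standard_normal(4) * mdd_noise
        thr = (spec.base_log_threshold + slope_per_size * W_SIZES
               + spec.ssc_sd * z_ssc + spec.ssi_sd * z_ssi * W_SIZES + eps)
        task_param = {}
        for task in TIMING_TASKS:
            lo = spec.timing_loading[task]
            resid = np.sqrt(max(1.0 - lo ** 2, 0.0))
            logv = (np.log10(spec.timing_base[task])
                    + spec.timing_sd[task]
                    * (lo * z_trp + resid * rng.standard_normal()))
            task_param[task] = 10.0 ** logv
        observers.append(ObserverParams(
            subject=i, mdd_log_threshold=thr,
            dd_jnd_empty=task_param["dde"], dd_jnd_filled=task_param["ddf"],
            tg_sd=task_param["tg"], rp_jnd=task_param["rp"],
            psychometric_slope=spec.psychometric_slope,
            lapse_rate=spec.lapse_rate, family=spec.family))
    return observers, latents


def generate_bis_subtests(spec: PopulationSpec, latents: pd.DataFrame,
                          rng) -> tuple[pd.DataFrame, dict]:
    """18 raw intelligence subtest scores per subject, plus the
    composite-mapping dict expected by ``protocols.score_bis``.

    Each composite (capacity, speed, memory) has a true score loading on g;
    its six subtests (2 figural, 2 numerical, 2 verbal) share that true
    score with reliability ``bis_subtest_r`` and are reported on an
    arbitrary raw scale (mean 100, SD 10).
    """
    z_g = latents["g"].to_numpy()
    n = z_g.size
    rho = spec.bis_subtest_r
    comps = ("capacity", "speed", "memory")
    contents = ("figural1", "figural2", "numerical1", "numerical2",
                "verbal1", "verbal2")
    data, mapping = {}, {}
    for lam, comp in zip(spec.bis_loadings, comps):
        true = lam * z_g + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
        cols = []
        for content in contents:
            sub = rho * true + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            name = f"{comp}_{content}"
            data[name] = 100.0 + 10.0 * sub
            cols.append(name)
        mapping[comp] = cols
    df = pd.DataFrame(data)
    df.insert(0, "subject", latents["subject"].to_numpy())
    return df, mapping


def population_threshold_cov(spec: PopulationSpec) -> np.ndarray:
    """Closed-form between-subject covariance of the four log thresholds
    (identity latent correlations assumed for the ssc/ssi block)."""
    ones = np.ones(4)
    resid = spec.noise_sds.get("mdd", 0.0) ** 2
    return (spec.ssc_sd ** 2 * np.outer(ones, ones)
            + spec.ssi_sd ** 2 * np.outer(W_SIZES, W_SIZES)
            + resid * np.eye(4))


# ---------------------------------------------------------------------------
# true response probabilities
# ---------------------------------------------------------------------------

def motion_p_correct(obs: ObserverParams, size_index: int, log_duration):
    """P(correct direction) at a log10-ms duration; 0.82 at the threshold."""
    fam = weibull_2afc if obs.family == "weibull" else logistic_2afc
    return fam(log_duration, obs.mdd_log_threshold[size_index],
               obs.psychometric_slope, 0.5, obs.lapse_rate, 0.82)


def dd_p_correct(obs: ObserverParams, delta_ms, variant: str = "empty"):
    """P(correct longer/shorter judgement) at absolute difference delta."""
    jnd = obs.dd_jnd_empty if variant == "empty" else obs.dd_jnd_filled
    return 0.5 + (0.5 - obs.lapse_rate) * np.tanh(np.abs(delta_ms) / (2.0 * jnd))


def tg_p_yes(obs: ObserverParams, duration_ms):
    """P("yes, that was the standard") for one test duration."""
    d = np.asarray(duration_ms, dtype=float)
    if obs.tg_sd <= 0.0:
        kernel = (d == TG_STANDARD).astype(float)
    else:
        kernel = np.exp(-((d - TG_STANDARD) ** 2) / (2.0 * obs.tg_sd ** 2))
    return obs.lapse_rate * 0.5 + (1.0 - obs.lapse_rate) * kernel


def rp_p_correct(obs: ObserverParams, x_ms):
    """P(correctly reporting "irregular") at deviant increment x."""
    return 0.5 + (0.5 - obs.lapse_rate) * np.tanh(np.asarray(x_ms) / (2.0 * obs.rp_jnd))


# ---------------------------------------------------------------------------
# single-trial responses
# ---------------------------------------------------------------------------

def respond_motion(obs: ObserverParams, size_index: int, log_duration: float,
                   rng) -> bool:
    if not 0 <= size_index < len(obs.mdd_log_threshold):
        raise IndexError("size_index out of range")
    return bool(rng.random() < motion_p_correct(obs, size_index, log_duration))


def respond_duration_discrimination(obs: ObserverParams, comparison_ms: float,
                                    rng, standard_ms: float = 50.0,
                                    variant: str = "empty") -> bool:
    if comparison_ms <= 0:
        raise ValueError("comparison duration must be positive")
    if comparison_ms == standard_ms:
        raise ValueError("comparison equal to standard: correctness undefined")
    p = dd_p_correct(obs, comparison_ms - standard_ms, variant)
    return bool(rng.random() < p)


def respond_generalization(obs: ObserverParams, duration_ms: float, rng) -> bool:
    if duration_ms not in TG_DURATIONS:
        raise ValueError(f"duration {duration_ms} not in stimulus set")
    return bool(rng.random() < tg_p_yes(obs, duration_ms))


def respond_rhythm(obs: ObserverParams, deviant_ms_x: float, rng) -> bool:
    if deviant_ms_x < 0:
        raise ValueError("deviant increment must be non-negative")
    return bool(rng.random() < rp_p_correct(obs, deviant_ms_x))
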