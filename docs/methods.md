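# Methods

## The generative observer model

A simulated subject is a draw from a four-dimensional latent distribution
over (η_TRP, η_SSC, η_SSI, η_g), standard normal margins with a
configurable correlation matrix. η_TRP is oriented as timing *badness*
(larger = poorer temporal resolution) so that it loads positively on the
four timing measures, on which smaller values always mean better
performance; η_g is intelligence. The default correlation matrix is not
free-form: it is constructed from structural paths — g regressed on
(TRP, SSC, SSI) with standardized coefficients (−.535, −.058, −.140),
r(TRP, SSC) = .353, r(TRP, SSI) = .180, SSC ⊥ SSI — so that a default
synthetic study has the effect sizes of the motivating large-sample study
and the combined structural model is correctly specified for the data it
will be fitted to.

Latents map linearly onto psychophysical parameters on a log10 scale:

* Motion thresholds (log10 ms at 82% correct, sizes 1.8–7.2 deg):
  `thr_s = 1.25 + (0.29/3)·w_s + √.022·η_SSC + √.003·η_SSI·w_s + ε_s`,
  `w = (0,1,2,3)`, `ε_s ~ N(0, 0.05²)`. The intercept and mean slope are
  calibrated so the mean thresholds (≈ 18–37 ms raw; 45–91 ms on the
  ×2.5 display-reporting scale) and the mean suppression index (.29)
  match the published descriptive table; the latent variances .022 and
  .003 are the published fixed-links estimates, which makes the
  fixed-links measurement model exactly the generative structure.
* Timing-task scales (discrimination JNDs, generalization noise, rhythm
  JND) are lognormal: `log10 θ_t = log10 base_t + sd_t·(a_t·η_TRP +
  √(1−a_t²)·δ)`. Base values (16.3, 7.8, 6.6, 49.6 ms) are backed out
  from the published task means via each task's psychometric model; total
  log-SDs (≈ .16–.19) from the published coefficients of variation; the
  loading fractions a_t (.55, .70, .58, .40) are set so that the *measured*
  task intercorrelations, after staircase measurement noise, resemble the
  published .16–.36 range. These are population descriptions fixed once;
  no individual-level data exist to estimate them from.
* Intelligence composites load on η_g with (0.776, 0.658, 0.593) — the
  closed-form triad solution of the published composite correlations — and
  each composite is expanded into six subtests (reliability .9 each,
  arbitrary raw scale) so that the z-standardize-and-average scoring step
  operates on realistic input.

Psychometric response models: motion direction is 2AFC with a Weibull (or,
by switch, logistic) function of log10 duration anchored to pass exactly
through 82% at the threshold, chance 0.5, lapse 0.01; duration and rhythm
judgements use a symmetric logistic `P = .5 + (.5−lapse)·tanh(Δ/2·JND)`;
generalization "yes" responses follow a Gaussian kernel around 75 ms with
width tg_sd plus a lapse floor. The lapse default (0.01) keeps thresholds
identifiable while acknowledging keypress errors; the family switch exists
because the functional form is a modelling convention, not an estimate.

## Adaptive procedures

*Bayesian tracker.* Uniform prior over a log10-ms threshold grid
(2–500 ms, step .01), likelihood from the assumed Weibull family (slope
3.5, chance .5, lapse .01, target .82), posterior-mean placement and
posterior-mean estimation, first trial at 80 ms. The prior, slope, grid
and estimator are internal conventions of such trackers rather than
published facts, so all are exposed in `QuestConfig`; the convergence
check used for validation (true percent correct at the estimate ≈ 82%) is
robust to these choices. A motion session is 3 blocks × 4 sizes × 2 runs
of 22 trials (the stated 44 trials per size per block yielding two
estimates), six estimates per size, drop the highest and lowest, average
the remaining four.

*Weighted up-down.* Steps +9/−3 ms for trials 1–6, +6/−2 ms from trial 7
(discrimination tasks; 32-trial series, two interleaved series with the
comparison above/below the 50-ms standard, start Δ = 30 ms — the start is
unstated in the source description and chosen mid-scale), +12 after an
incorrect / −4 after a correct response for rhythm (start x = 20 ms). The
printed rhythm step directions (up after correct) cannot converge to a
75% threshold and are implemented in the direction that does
(equilibrium 12/16 = .75). Thresholds are the mean presented level of the
last 20 trials. A floor at 1 ms prevents non-physical differences, and
the below-standard series is additionally capped so the comparison stays
positive.

Two small biases of these procedures are worth naming because tests and
validation account for them. First, the zero-drift equilibrium fixes
E[P(level)] = .75 over the stationary distribution, while the reduction
evaluates P(mean level); because the psychometric function is concave
there, this carries a positive bias of order (step/JND)². Convergence
checks therefore use a smooth observer (JND well above the steps);
study-scale observers are not in that regime, which is a property of the
real procedure, not an implementation artifact. Second, a 32-trial series
starting far from the observer's 75% point retains transient trials in
its last-20 window; rhythm thresholds of insensitive observers are
therefore biased toward the 20-ms start, again mirroring the real design.

## Measure reduction and screening

SI is the difference of the two log-scale thresholds (the thresholds are
already log10 values; a second log would be dimensionally incoherent and
inconsistent with the published SI range). The dispersion index divides
the relative yes-frequency to the standard (16 presentations) by the
summed relative frequencies over all seven durations (8 presentations
each); "inversion" for analysis is `1 − index`, a strictly decreasing
affine map that leaves all correlation magnitudes unchanged. If a subject
never answers "yes" the index is undefined and is set to 1/7 — the value a
completely insensitive observer approaches — and flagged. The outlier rule
removes subjects above mean + 3 SD (one-sided: all screened variables are
poor-performance-high) on any of the four timing measures or the 1.8-deg
threshold, in one pass with statistics from the unfiltered sample; a
two-sided switch exists but is off by default.

## The covariance-model engine

Models are specified as pattern matrices (fixed value / free slot) for
Λ (p×m loadings), Ψ (latent or disturbance covariances), Θ (residual
covariances) and B (latent paths), with implied covariance
Σ = Λ(I−B)⁻¹Ψ(I−B)⁻ᵀΛ′ + Θ. Estimation minimizes
F_ML = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p with the analytic gradient
(E = Σ⁻¹ − Σ⁻¹SΣ⁻¹; ∂F/∂Λ = 2EΛΦ and the corresponding expressions for
Ψ, Θ, B), L-BFGS-B under box constraints, positive-definiteness enforced
through Cholesky evaluation, followed by a damped Newton polish with a
numeric Hessian; convergence is declared on the Newton decrement, which is
scale-aware where a raw gradient norm is not (variances of order 10⁻³
carry curvatures of order 10⁵). Jittered multi-starts (up to 5) run if
the decrement stays large. Start values are data-informed (loadings
0.7·√s_ii, residuals s_ii/2) unless the pattern provides them.

Conventions: T = (n−1)·F_ML; baseline for CFI is the independence model,
whose ML solution is closed-form (T_b = −(n−1)·ln|R|); RMSEA =
√(max(T−df,0)/(df(n−1))); SRMR over all p(p+1)/2 unique correlation-metric
residuals; AIC = (n−1)(ln|Σ̂| + tr(SΣ̂⁻¹)) + 2q, i.e. −2·loglik dropping
the data-only constant, so only AIC *differences* are meaningful.
"Greater than zero" variance restrictions are box bounds at 10⁻⁶.
Negative variance estimates at an interior optimum raise a Heywood
warning with a bound suggestion rather than being silently truncated.

Robust (Satorra–Bentler) scaling keeps the ML estimates and divides T by
c = tr(UΓ̂)/df, with Γ̂ the distribution-free fourth-moment estimate of
the asymptotic covariance of vech(S) and U the normal-theory weight
matrix projected off the model tangent space (numeric Jacobian of
vech(Σ)). One consequence checked explicitly in the tests: with
*independent* non-normal factors and errors the unscaled statistic is
asymptotically robust and c ≈ 1; inflation (c > 1) appears for elliptical
heavy tails (common scale mixing), which is what the robust correction
exists for.

Reliability uses ω_f = (1′Λ_f)²·Φ_ff / (1′Σ̂1) over the factor's
indicators, which reduces to (Σλ)²/((Σλ)²+Σθ) in the standardized
congeneric case. Factor scores default to the regression (Thomson) method
ΦΛ′Σ̂⁻¹(x−x̄); Bartlett scoring is available — the source analyses do not
state which was used, so the default is documented rather than asserted.
Modification indices are univariate score tests
MI = ½·g_c²·[H⁻¹]_cc on the chi-square scale (gradient and numeric
Hessian over free parameters plus the candidate), computed for every
fixed residual and latent covariance; they approximate the T drop from
freeing one parameter and are validated against actual refits (15%
contract) and a planted-covariance design.

Fixed-links caveat: because the loadings (1,1,1,1) and (0,1,2,3) are
fixed *numbers*, the model is not scale invariant — fitting the
correlation instead of the covariance matrix changes the standardized
solution (a test asserts the difference). All fixed-links fits therefore
run on log10-threshold covariances, the only scale on which the latent
variances .022/.003 are meaningful.

## Study models and pipeline

The registry encodes: one-factor CFAs for g (3 indicators, exactly
identified, df = 0), the timing factor (df = 2) and a congeneric
suppression model (df = 2); the fixed-links suppression model with the
free 3.6–5.4-deg residual covariance and bounded first/fourth residual
variances (df = 3); latent regressions of g on TRP (df = 13) and on
SSC + SSI (df = 13); the TRP–suppression correlation model (df = 19); and
the combined model (df = 40). Endogenous g is scale-fixed through its
first loading, exogenous factors through unit variance; standardization
is computed afterwards from the implied covariances. `run_study` executes
simulate → tasks → screen → descriptives → threshold ANOVA →
correlations (g factor scores from the exactly identified CFA) →
measurement models → AIC comparison → structural models, with per-stage
failure records; timing and intelligence measures are z-scored for the
structural fits while thresholds stay on their log scale.

## Parameter recovery

The recovery experiment draws subject × measure data *directly from the
latent model* (thresholds from the fixed-links structure including a true
3.6–5.4 residual covariance of .002 and residual variances .0049; timing
and composite indicators from their standardized loadings; g from the
−.535 path) and refits the registry models — 200 replicates at n = 273
by default, reporting mean estimate, bias and Monte-Carlo SE for φ_c,
φ_i, the standardized TRP→g path and optionally the latent correlations.
Trial-level noise is deliberately excluded here: the recovery question is
whether the estimator is unbiased for the model that generated the data.
End-to-end behaviour with trial-level noise is covered separately by the
pipeline tests, where adaptive-procedure measurement error attenuates
observed loadings — which is also why the generator's loading fractions
sit above the published manifest correlations.

## Problem sizes and numerical tolerances

Default suite sizes: populations of 25–273 subjects for pipeline tests,
10⁴-subject draws for distributional checks, 10⁴ staircase trials and 500
tracker replications for convergence checks, 200 replicates for recovery,
20 random models for optimizer-equivalence (|ΔF| < 10⁻⁸ against an
independent Nelder–Mead minimization of an independently coded F_ML).
Statistical cross-checks run against brute-force moment/sum-of-squares
oracles (10⁻¹⁰), pingouin's repeated-measures ANOVA, scipy, and R's
`factanal` for one-factor ML loadings. Mauchly's p uses the first-order
chi-square approximation (pingouin adds a second-order term; W and the
chi-square statistic agree exactly).

## Known limitations

* Simulated observers are stationary: no practice, fatigue or
  session-order effects, no display-frame quantization (continuous
  durations), no auditory rendering. Passing tests show the analysis
  chain recovers the generative structure, not that real data obey it.
* Real-sample point estimates that depend on the undeposited raw data
  (e.g. the printed structural chi-squares) are reproduced only as
  qualitative contracts on matched synthetic data.
* The η² flavour behind the published ANOVA effect size is ambiguous;
  classic, partial and generalized variants are all reported and none is
  treated as the target.
* Whether published chi-squares labelled robust are scaled or unscaled is
  not always decidable; both T and T_SB are reported for every fit.
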