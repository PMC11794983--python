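# Methods

## The generative model

Activity is modelled on the diel (24-hour) cycle. For site *i* and
time-of-day *t* (hours), the probability that the species is active is

    logit p_i(t) = β0 + β1 cos(2πt/ω1 + θ0 + γ_i)
                      + β2 cos(2πt/ω2 + θ1 + γ_i) + τ_i,

with harmonic periods ω1 = 24 and ω2 = 12 hours, amplitudes β1, β2 ≥ 0
(signs are absorbed into the phases θ0, θ1), a site random intercept
τ_i ~ N(0, σ_τ) capturing variability in frequency of site use, and a site
random phase γ_i ~ N(0, σ_γ) shifting both harmonics, capturing variability
in the timing of activity. Detections per site × day × bin are Bernoulli
draws; aggregated over days they are binomial.

The simulator (`dielact.sim`) evaluates probabilities at **bin start** times
(t = 0, Δ, 2Δ, …) and emits one detection record per successful bin — the
binary model cannot represent within-bin multiplicity, so none is simulated.
A single integer seed drives everything; site effects are drawn before
observation noise, so the same seed yields the same sites whatever is
sampled afterwards. Default parameters are β0 = −3, β1 = 1, β2 = 0.7, θ0
placing the 24-h harmonic's peak at 20:00, θ1 = 0, σ_τ = 1, σ_γ = 0.3 —
chosen once to give realistic camera-trap sparsity (detection probabilities
mostly 0.02–0.2 per site-hour-day) and clear bimodality. Note that with both
harmonics active the *summed* curve peaks near 23:15, not at 20:00.

What the simulator does **not** emulate: detection-distance or sensor
imperfection, within-site temporal autocorrelation beyond the site effects,
covariates that vary within a sampling day, or seasonal drift within a
deployment. Tests passing on simulated data therefore demonstrate the
estimators' statistical correctness under the stated model, not robustness
to every feature of field data.

## Occasion construction

Detections plus a deployment (effort) table become binary occasions
capt_itj ∈ {0,1}: 1 iff ≥ 1 detection at site *i* in bin *t* on day *j*,
with rows only for sampled site-days. Bins are half-open [t, t+Δ) labelled
by start hour. By default a site-day-bin counts as sampled only when the
deployment covers the whole bin (`effort_mode="full"`); an any-overlap mode
exists because field deployments rarely start at midnight and the full-bin
rule discards the partial first/last day. Aggregation to binomial
(success, failure) counts is per site × bin and, when categorical covariates
are present, per covariate level; covariates live on the *effort* table
because failure days have no detection record to carry them, and they must
be constant within a site-day (aggregation refuses otherwise).

The independent-event filter (for the KDE baseline only) scans each site
chronologically and keeps a record iff ≥ threshold minutes passed since the
last **kept** record — the common camera-trap convention; anchoring on the
last *seen* record is available by flag. The hierarchical models do not need
this filter: near-simultaneous records fall into the same bin anyway.

## Trigonometric GLMM

The compound-angle identities linearize each cosine:
β·cos(2πt/ω + θ) = α_c cos(2πt/ω) + α_s sin(2πt/ω) with α_c = β cos θ,
α_s = −β sin θ. The fixed-effect design is intercept, cos/sin per period
(periods sorted descending, cos before sin, so coefficient order matches the
α1…α4 convention), covariate main effects, and optional covariate × harmonic
interactions. Random structures: intercept only (default), intercept plus
independent ("diagonal") slopes on the harmonic columns, or correlated
slopes via a log-Cholesky parameterization. Periods [] / [24] / [24, 12]
express the cathemeral / unimodal / bimodal shape hypotheses.

The marginal likelihood integrates the site effects numerically with
adaptive Gauss–Hermite quadrature: per site, an inner damped Newton finds
the posterior mode of the standardized effects, the integrand is re-centred
and re-scaled there, and a product Gauss–Hermite grid (default 11 nodes for
one dimension, 7 per dimension for 2–3) evaluates the integral; one node is
exactly the Laplace approximation, used automatically above 3 dimensions.
Modes are warm-started across likelihood evaluations. SDs are optimized on
the log scale; a non-finite or exploding proposal returns a large barrier
value rather than crashing. Outer optimization is BFGS with 3-point
finite-difference gradients from deterministic starts (fixed effects from
the no-random-effect GLM via statsmodels; all SDs at 0.3); convergence is
declared at gradient sup-norm ≤ 1e-4 and reported with the fit. The
parameter covariance is the inverse of a central-difference observed
information at the optimum, so Wald intervals for σ_τ are computed on the
log scale and exponentiated.

Model comparison uses marginal AIC = −2·loglik + 2·df with the transparent
df convention df = #fixed + #variance parameters (the intercept-only null
model has df = 2), and likelihood-ratio tests with the statistic clipped at
zero and χ² reference distribution. AIC/LRT comparisons check that the fits
share a data fingerprint. LRT p-values near the 0.05 boundary should be
read cautiously when the tested parameters include variance components
(boundary effects make the χ² reference conservative).

## Cyclic-spline HGAM

The cyclic cubic regression spline is parameterized by the function's values
at K knots (default 12, equally spaced on [0, 23] so hour 23 wraps onto hour
0 — matching common practice on hourly-binned data; knots spanning [0, 24]
are available by config and recommended for sub-hourly analyses). The
natural-spline conditions give the knot second derivatives as B⁻¹D times the
knot values; the wiggliness penalty is S = DᵀB⁻¹D, symmetric PSD with
constants as its null space. Each cyclic smooth gets a sum-to-zero
constraint for identifiability next to the intercept (replicated in spirit
from standard GAM practice, not bit-for-bit). By-factor smooths replicate
the centred basis per level; the site random intercept is a ridge-penalized
indicator smoother whose smoothing parameter λ maps to an implied
random-intercept variance σ_τ² = 1/λ.

Fitting is penalized IRLS (with step halving) inside quasi-Newton
optimization of the Laplace-approximate REML criterion over log-smoothing
parameters, bounded to [−18, 18]. Effective degrees of freedom are
per-block traces of (XᵀWX + S_λ)⁻¹XᵀWX; AIC = −2·loglik + 2·edf_total with
*plain* edf — no correction for smoothing-parameter uncertainty — so AIC
values differ slightly from software that applies one, though differences
and orderings are robust. The reported coefficient covariance is the
Bayesian posterior covariance (XᵀWX + S_λ)⁻¹. The two covariate structures
(`season_structures`) are (1) covariate main effect + per-level time smooth
+ site ridge, and (2) the same plus a global time smooth and a by-site time
smooth; the by-site smooth shares one smoothing parameter across sites (the
factor-smooth convention) to keep the outer optimization low-dimensional.
AIC comparisons between structures with and without a global smoother are
flagged, as AIC favours the structure without it. An independent check
against R mgcv's `gam(..., bs="cc", method="REML")` on simulated data
reproduces the fitted curve to ~1e-8 and the implied σ_τ to four digits
(see tests).

## Curves, intervals, peaks

Conditional (typical-site) curves set random effects to zero; site-specific
curves add the site's posterior-mode effects. Marginal curves integrate
logit⁻¹ over the estimated random-effect distribution. Because the site
contribution z(t)ᵀb is scalar Gaussian with SD √(z(t)ᵀD̂z(t)) at each time
point, the integral reduces exactly to one-dimensional Gauss–Hermite
quadrature (25 nodes) whatever the random-effect dimension — no Monte Carlo
is needed for the point estimate. For HGAM fits the marginal integrates over
the implied site-intercept distribution only; by-site smooth curvature is
conditional-only (flagged limitation).

Conditional 95% intervals are Wald on the linear predictor, back-transformed
(so bounds respect [0, 1]). Marginal intervals are percentile intervals over
seeded draws of the fixed effects from N(β̂, V̂) propagated through the
marginal integral; uncertainty in the random-effect variance is deliberately
not propagated (reproducible, slightly narrow). Peak finding is wrap-aware
local-maximum detection on a 1-minute grid, ties broken by earlier time;
a flat curve has no peaks.

## KDE baseline

Detection times map to angles (2πt/24) and the density is a von Mises kernel
mixture. The kernel concentration uses the standard plug-in rule for von
Mises kernels (fit a von Mises by maximum likelihood, κ̂ from the mean
resultant length, then κ_kernel = [3nκ̂²I₂(2κ̂)/(4√π I₀(κ̂)²)]^{2/5}), with an
`adjust` multiplier because results are sensitive to the bandwidth choice;
a sample with zero circular variance has no defined bandwidth and is
rejected. Exponentially scaled Bessel functions keep large-κ evaluation
stable. Uncertainty is a pointwise percentile bootstrap over detections —
which assumes independent observations, precisely the assumption the
hierarchical models relax; with strong site heterogeneity the KDE's bands
understate uncertainty. KDE output is a relative density (integrates to 1),
not a probability of activity, and corresponds to a marginal, not
conditional, pattern.

## Workflows, configuration, reproducibility

The shape workflow fits the null/unimodal/bimodal trio and reports the AIC
table, LRT chain, and the winning model's curve; a failed member yields a
partial report, never a silent drop. The covariate workflow fits the trig
GLMM with covariate × harmonic interactions (plus the no-covariate null on
identical data rows for a fair ΔAIC), both HGAM structures, and per-level
KDEs. Configs are strict-validated (unknown keys rejected); one top-level
seed fans out to per-component child seeds via named SeedSequence spawning,
so adding a model does not perturb the others' randomness. Every run writes
a manifest with input checksums, seed and versions.

## Problem sizes and numerical defaults

Replicated experiments in the test suite use sizes chosen to make their
statistical targets detectable with comfortable margins: parameter-recovery
coverage runs 100 replicates of 100 sites × 60 days; shape-selection
operating characteristics run 100 replicates of 50 sites × 30 days; the
acceptance script uses 40 replicates of the same designs. Quadrature: 25
nodes against brute-force oracles, 11 in routine fits (fits are insensitive
beyond ~7 nodes for one dimension). Optimizer tolerances: BFGS gradient
norm 1e-5 (convergence accepted at ≤ 1e-4), inner Newton gradient 1e-9,
PIRLS penalized-deviance change 1e-10.

## Known limitations

- Logit link only; no Poisson/count formulation.
- No crossed random effects and no temporal autocorrelation beyond the site
  effects; no spatial or spatiotemporal random fields.
- Random phase effects enter the fitted model only through random slopes on
  the harmonic columns (the linearization is exact for fixed phases but the
  slope distribution is an approximation to a distribution on phases).
- Timestamps are taken at face value: no time-zone or daylight-saving
  arithmetic, and no sunrise/sunset rescaling.
- HGAM p-values for smooth terms are not provided; LRT between HGAMs is
  avoided on purpose (smoothing-parameter selection uses the data twice).
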