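# Methods

This note documents the generative model, the estimators, the calibration
of the experiment templates, and the numerical choices, in enough detail to
reproduce or audit any number the package emits.

## Choice model and observer simulation

A simulated observer performs a two-interval duration comparison by the
method of constant stimuli. On a trial with signed duration difference
`delta` (communicative − noncommunicative, in ms) the probability of
judging the communicative sequence longer is

    p(delta) = lapse/2 + (1 − lapse) · F(delta; x0, ω),
    F(x) = 1 / (1 + exp(−(x − x0)/ω)),  ω > 0,

with per-observer latent parameters x0 (the PSE) and ω (slope). The lapse
rate defaults to 0 — the fitted model downstream has no lapse term, and a
non-zero default would bias fits by construction; it exists only for
robustness experiments. Responses are independent Bernoulli draws;
presentation order and standard-assignment flags are recorded on each trial
but do not enter the choice model, since no order effect is part of the
analysis being validated.

The default design is 7 levels (−600 … +600 ms in 200 ms steps), 20 trials
per level per condition (140 trials, presented in 4 shuffled blocks of 35).

Populations are described by `PopulationSpec`:

* AQ (Autism Spectrum Quotient, integer trait score): normal with stated
  mean/SD, truncated to a stated range (window widened by ±0.5 before
  rounding so edge integers remain reachable), rounded to integers. The
  trait distribution's form is a modeling choice; only its first two
  moments and range are calibrated.
* Latent PSE per condition c:
  `PSE(c) = intercept(c) + slope·AQ + u + eps(c)`, with `u ~ N(0, σ_obs)`
  shared across conditions (inducing the within-observer correlation that a
  paired design exploits) and `eps(c) ~ N(0, σ_cond)` condition-specific.
* ω: normal (mean `omega_mean_ms`, SD `omega_sd_ms`), floored at 1 ms,
  shared across conditions — difference limens are modeled as
  condition-invariant, matching the repeated finding that temporal
  sensitivity does not change across the contrasts of interest.
* Drug effects (oxytocin / atosiban / saline) are a single additive shift
  of all latent PSEs, `N(shift_mean, shift_sd)` across observers, leaving
  ω untouched.

`calibrate_aq_pse_link(target_r, pse_sd, …)` moment-matches the AQ→PSE
link: `slope = r·σ_PSE/σ_AQ`, `resid = σ_PSE·√(1−r²)`, where σ_AQ is the
*effective* SD of the truncated, rounded trait distribution, measured once
on a large fixed internal sample (deterministic). A Monte-Carlo test at
n = 10,000 verifies the realized correlation to ±0.02.

All randomness flows from one root seed through named CRC-keyed substreams
(`population`, `trials`/observer/condition, `drug`, `bootstrap`), so any
stage re-run in isolation reproduces its output bit for bit.

## Psychometric estimation

Choices are tallied into per-level counts and fitted by maximum likelihood
on the binomial counts (default) or least squares on the proportions (for
sensitivity checks). The curve is parametrized in its increasing form with
ω > 0; the equivalent decreasing convention differs only by ω ↦ −ω, and
the DL is |ω|·ln 3 under either.

**MLE.** In the logit parametrization η = β₀ + β₁x (β₁ = 1/ω,
x0 = −β₀/β₁) the negative log-likelihood is convex, so a safeguarded
Newton iteration (analytic 2×2 Hessian, backtracking line search, tolerance
10⁻¹⁰ on the objective) reaches the global optimum from a moment-based
start — no multi-start is needed, and each fit costs ~50 µs, which is what
makes 200 end-to-end replicates of all six experiments affordable. Tests
verify optimality against two independent oracles: an exhaustive 1 ms-grid
search over (x0, ω) and a binomial GLM fitted by IRLS (statsmodels).

**Least squares** minimizes squared error on proportions with bounded
`scipy.optimize.least_squares` from 3 starts (moment-based, centered, and
double-width), since that objective is not convex.

Estimates are confined to x0 ∈ [−1200, 1200] ms, ω ∈ (0, 2000] ms.
Degenerate data are flagged, never dropped silently, and always yield
finite estimates with `converged=False` and a warning:

* all responses identical → x0 pinned at the box edge, ω at 2000 ms;
* perfectly separated responses (all 0s then all 1s) → x0 at the gap
  midpoint, ω the shallowest step consistent with the gap;
* flat proportion profiles (slope not identifiable, e.g. all 0.5) → ω
  clamps to 2000 ms.

Downstream group statistics exclude non-converged fits and report the
exclusion count. The DL of a non-converged fit propagates as NaN.

At the default design (20 trials/level) the asymptotic sampling SD of one
fitted PSE is ω/√(R·Σₗ pₗ(1−pₗ)) ≈ 0.32·ω — about 32 ms at ω = 100. A
recovery test over 1,000 simulated observers checks that the mean fitted
PSE is within 5 ms of truth with |bias| < 2 SE, at both x0 = 69.3 and 0.

## Inferential conventions

* One-sample/paired d = t/√n; independent d = t·√(1/n₁+1/n₂). These
  conventions are fixed by reverse-engineering every published effect size
  they must reproduce; all pass at 2-decimal precision.
* Independent t-tests pool variances (df = n₁+n₂−2, as the published df
  imply), not Welch. All p-values two-sided; no multiplicity correction.
* Mixed ANOVA (within: orientation; between: experiment) is delegated to
  `pingouin.mixed_anova`; the interaction row is returned with partial η²
  and Cohen's f = √(η²ₚ/(1−η²ₚ)). A from-scratch sum-of-squares
  decomposition serves as the test oracle. When the interaction SS is
  exactly zero (all cells equal) F is defined as 0 rather than 0/0.
* Median split: threshold T chosen so groups read "score < T" vs
  "score ≥ T"; when the median is attained, T is the smallest integer
  strictly above it (median 19 → groups <20 / ≥20). Empty groups warn.
* The bootstrap resamples whole observers (pre, post) pairs with
  replacement, 1000 resamples by default, each contributing its bivariate
  sample mean. Percentile summaries only; no BCa correction.

## Template calibration

Templates encode the published sample sizes (24, 24, 24, 90, 40+40,
40+40) and group means (e.g. upright 69.3 ms in the orientation
experiment; baseline 13.3/9.7 ms and shifts +36.9/−19.1 ms in the high-AQ
drug arms; baseline 48.6/54.5 ms and shifts −31.1/0 ms in the low-AQ
arms). Where generating means are unreported (inverted conditions, the
intent-disrupted experiments), 0 is used.

Between-observer SDs are back-solved from published t statistics,
SD = mean·√n/t. Crucially, such an SD describes *fitted* PSEs and thus
already contains single-fit estimation noise. The latent SDs therefore
deconvolve it: `σ_latent² = σ_observed² − m·var_fit`, with m = 1 for a
single-session quantity and m = 2 for a pre/post change score. Two
consequences:

* The published change-score SDs (43–50 ms) bound the single-fit noise
  from above, which bounds ω: with ω = 150 the two-session noise floor
  alone would exceed some published SDs. The template default is
  ω ~ N(100, 20) ms, i.e. DL ≈ 110 ms — a Weber fraction of ≈11% at the
  1 s standard, in the normal range for duration discrimination. The
  saline change SD deconvolves to ≈0: practice/fatigue-free stability.
* The orientation template splits its total SD (60.6 ms) into a shared
  observer component (≈51 ms) and a condition-specific one (≈19 ms after
  deconvolving the paired-difference SD of 58.3 ms), so both the
  one-sample and the paired contrasts have realistic operating
  characteristics.

The AQ-correlation template targets the published observed r = −0.40
between AQ and fitted PSE. Since fit noise attenuates correlations but not
covariances, the latent link is steeper: r_latent = r_obs·σ_obs/σ_latent.
The AQ distribution for that sample (unreported beyond its median of 19) is
N(19.5, 6) truncated to [10, 36]. All template parameters are plain
constructor arguments and can be overridden.

These back-solved SDs are approximations — printed SEs readable only from
figures are not used.

## Replication-fidelity checks

`headline_checks` encodes, per experiment, which published findings a
replicate must reproduce. Contrasts whose published effect sizes give high
power at the published n are held to significance at α = 0.05 (upright
compression; AQ correlation; oxytocin increase and the oxytocin-vs-atosiban
change difference; the low-AQ atosiban drop); true-null contrasts are held
to *non*-significance (inverted condition; saline arm); and contrasts whose
own published effect sizes imply power below the 80%-of-replicates bar
(the high-AQ atosiban change, d = −0.35; the low-AQ between-group change
difference, d = 0.50; the median-split group difference as realized under
the correlation-calibrated model) are held to direction only. DL contrasts
must stay non-significant, mirroring the condition-invariant ω. The
acceptance checks run 200 end-to-end replicates per experiment and require
≥ 80% joint pass rates (≥ 85% for DL).

The omnibus orientation × experiment interaction's power claim is verified
at the latent-PSE level (100 replicates; fit noise is small against the
between-observer SD there), and end-to-end once for its degrees of freedom
(2, 69 with 72 pooled observers).

## Problem sizes and runtime

Defaults were chosen so the full validation suite runs in minutes on one
CPU: 50 observers for the grid-oracle comparison (the 1 ms grid costs
~1.2M likelihood evaluations per observer), 1,000 observers per recovery
condition, 10,000/2,000 null datasets for the t/ANOVA type-I rates, and
200 end-to-end replicates per experiment for fidelity.

## What passing does and does not show

The synthetic populations have normal trait and PSE distributions,
independent trials, no lapses, no sequential or order effects, no
practice/fatigue drift (saline stability is built in, not emergent), and
condition-invariant ω by construction. Passing therefore validates the
*pipeline* — estimator correctness, calibration of test procedures, and
faithful reproduction of the published statistical structure under a
plausible generative model — not any claim about new human data. Exact
published group means are not reproducible (no trial-level data are
deposited); they enter as generative parameters and directional targets
only.

## Known limitations

* No lapse-rate estimation; heavy lapsing would bias PSE/ω fits.
* No hierarchical (shrinkage) estimation; each observer is fitted alone.
* The mixed ANOVA assumes balanced within-observer data and, with two
  within levels, needs no sphericity correction; other designs would.
* Drug effects are purely additive on the latent PSE; dose-response,
  time-course and interactions with ω are out of scope.
* Back-solved SDs inherit the rounding of the published statistics.
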