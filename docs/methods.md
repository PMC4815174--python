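# Methods

## The question being simulated

Recorded reaction times are the sum of the participant's true response time
and a technical delay contributed by input devices, operating-system timers
and (for web experiments) the browser event loop. `rtnoise` models that delay
as an additive, per-trial, independent uniform random variable — by default
U(10, 100) ms — and asks how it distorts the parameters recovered when a
distributional RT model is fitted by maximum likelihood. The delay model is a
deliberately pessimistic stand-in: benchmark studies of keyboards, mice and
browser timing APIs report mean delays of roughly 15–35 ms with device- and
software-dependent spread, so a uniform 10–100 ms band brackets most realistic
setups; the sweep pipeline (`run_noise_sweep`) covers upper bounds from 50 to
200 ms for sensitivity analysis.

All data are generated internally; nothing is fitted to empirical recordings.
The generator's defaults are the study conditions of the simulation design the
package implements, and are not meant to be tuned per run:

| quantity | default | units |
|---|---|---|
| ex-Gaussian priors | μ ~ U(450, 550), σ ~ U(25, 75), τ ~ U(50, 150) | ms |
| trials per data set (ex-Gaussian) | 80 | – |
| diffusion priors | a, v, T<sub>er</sub> each ~ U(0.15, 0.25) | s = 0.1 scale |
| trials per data set (diffusion) | 100 | – |
| technical delay | U(10, 100) per trial | ms |
| recovery iterations | 500 (1000 per level in the noise sweep) | – |
| effect-size grid | 10, 20, 30, 40, 50 on μ, σ or τ | ms |
| simulated participants | 500 | – |

Within an iteration the noisy data set is always the clean data set plus a
fresh delay draw — never an independent redraw — so the clean/noisy fit pair
shares its sampling error, which is the comparison the bias regression is
designed around. One master seed drives named substreams (priors, trials,
noise, per iteration/participant), so any run is exactly reproducible and
iterations could be evaluated in any order.

## Ex-Gaussian model

Density of the exponentially-modified Gaussian with parameters (μ, σ, τ), all
in milliseconds. The log-density is evaluated as

log f(x) = −log(2τ) − z²/2 + log erfcx(u/√2),  z = (x−μ)/σ, u = σ/τ − z,

using the scaled complementary error function so the exp((σ/τ)²) factor of
the textbook formula never overflows. For u < −25 (deep right tail) erfcx
itself overflows and the code switches to the exact exponential-tail
asymptote log f = −log τ + σ²/(2τ²) − (x−μ)/τ; the switch error is below
1e−12 there. The density is cross-checked in the tests against an independent
quadrature convolution of the normal and exponential densities and against
`scipy.stats.exponnorm`.

Fitting maximises the exact log-likelihood with a Nelder–Mead simplex on
(μ, log σ, log τ); the log transform enforces positivity without constraints.
Starting values are moment-based and deterministic: τ₀ = 0.8 s, μ₀ = x̄ − τ₀,
σ₀ = √max(s² − τ₀², (0.1 s)²) with s the sample SD — a standard heuristic for
this model that starts the exponential component at most of the observed
skew. A failed convergence triggers one restart from a ±10 % multiplicatively
jittered start (jitter drawn from a fixed-seed generator, so fits stay
deterministic); persistent failure is flagged on the results object and the
pipeline drops that iteration pairwise from the bias regression, reporting
the count. Fits require at least 10 observations with non-zero variance —
below that the three-parameter likelihood is ill-posed.

## Diffusion model

A Wiener process with drift v starts at z between absorbing boundaries 0 and
a; absorption at a is a correct response, at 0 an error, and observed RT is
the first-passage time plus T<sub>er</sub>. The within-trial diffusion
coefficient s is a scale convention, fixed at 0.1 so that the U(0.15, 0.25)
priors sit in the conventional parameter range. The starting point is pinned
at z = a/2 (no response bias) and the across-trial variability parameters are
fixed at zero throughout.

**Simulation** is an Euler–Maruyama walk with step dt (5e−4 s in the
pipelines, 1e−4 s for oracle comparisons), increments v·dt + s·√dt·N(0, 1).
Because a discrete walk only inspects the path on the grid, it misses
boundary crossings between steps and systematically overestimates passage
times; both boundaries are therefore shrunk inward by the Broadie–Glasserman
continuity correction 0.5826·s·√dt, which removes the leading-order bias. At
dt = 1e−4 the corrected simulator agrees with the analytic first-passage
density to a Kolmogorov–Smirnov distance of about 0.003 at n = 200 000.
Walks exceeding a 60 s cap are redrawn and counted (`n_resampled`).

**Densities.** The defective first-passage density at each boundary is the
classical two-boundary Wiener series, evaluated in unit-diffusion scaling
with the small-time (image sum) or large-time (eigenfunction) representation
chosen per time point by the standard term-count rule with absolute
truncation error below 1e−10. The defective CDF integrates the eigenfunction
series term by term in closed form; density and CDF are mutually
cross-checked in the tests, as is the closed-form absorption probability
(1 − e^(−2vz/s²)) / (1 − e^(−2va/s²)).

**Fitting.** Two objectives are implemented, both with only (a, v,
T<sub>er</sub>) free:

* `method="quantile"` (default): multinomial likelihood of the observed
  counts between the per-boundary RT quantiles (.1, .3, .5, .7, .9), with
  expected bin probabilities from the defective CDF. Boundaries with fewer
  than 10 responses are reduced to a median split, below 4 to their total
  probability mass only. This is the objective class used by the established
  diffusion-fitting toolboxes, and at 100 trials it reproduces their
  characteristic finite-sample fingerprint — a and v overestimated,
  T<sub>er</sub> underestimated — which the continuous likelihood does not.
* `method="continuous"`: exact per-trial likelihood of (RT, response) under
  the defective densities; trials with rt ≤ T<sub>er</sub> contribute a
  smooth penalty −10⁶·(T<sub>er</sub> − rt + 1e−4) instead of a −∞ cliff so
  the simplex is repelled rather than trapped. Preferable for large samples.

Starting values are the EZ-diffusion moment estimates (accuracy, correct-RT
mean and variance in closed form), edge-corrected for accuracies of 0, ½
or 1 and clipped to a sane box, with a generic fallback when the formulas
are undefined. The optimiser is the same Nelder–Mead scheme as the
ex-Gaussian fit, including the seeded jittered restart. Fits with under 50
trials or a silent boundary are flagged `low_information` rather than
refused.

## Bias regressions and the noise sweep

For each parameter, the pipeline regresses noisy-fit on clean-fit values by
OLS (statsmodels), with classical t-based 95 % CIs. The intercept is tested
against 0 and the slope against 1; both p-values are emitted (plus the
conventional slope-vs-0 p for completeness), and significance flags follow
the CI-exclusion rule. Iterations with a failed fit in either version are
dropped pairwise and counted. The sweep pipeline repeats the ex-Gaussian
study for delay upper bounds 50–200 ms (step 10, 1000 iterations per level,
independent substream per level) and summarises coefficient trends by
weighted least squares with weights inversely proportional to each level's
CI width, so noisier levels count for less.

## Effect sizes and power

The effect-size pipeline simulates a within-subject experiment: each
participant gets base parameters from the priors, a control condition at
those parameters and an experimental condition with one parameter shifted by
a fixed effect (10–50 ms), 80 trials each, each in a clean and a delayed
version. Fitted parameter values are compared across participants by a
paired t-test; Cohen's d is the paired-design conversion d = t/√n. Required
sample size is the smallest n ≥ 2 whose two-tailed paired t-test at α = .05
reaches 80 % power under the noncentral t distribution with df = n − 1 and
noncentrality d·√n — the same computation G*Power performs — found by exact
integer search and confirmed against a Monte-Carlo power simulation in the
tests. Identical control/experimental vectors return t = d = 0; a non-zero
constant difference (zero within-pair variance) is an error.

## Numerical and design notes

* Simplex tolerances are xatol 1e−6 / fatol 1e−8, tight enough that refitting
  from a previous optimum never lowers the log-likelihood by more than 1e−6.
* The ex-Gaussian normal limit (τ → 0) approaches the normal density through
  a mean shift of exactly τ; tests therefore compare against the τ-shifted
  normal at first order.
* τ̂ carries a genuine downward small-sample bias at low τ (about half a
  standard error at 80 trials), so clean-fit-versus-veridical regressions
  have slopes slightly above 1 at 500 iterations; the recovery checks bound
  tracking quality (correlation, mean bias, slope within 15 %) rather than
  asserting exact identity.
* Binary significance flags on genuinely null coefficients flip on roughly
  1 in 10 replications at the 5 % level; reproduction tests for the τ row
  accordingly bound effect magnitudes instead of re-testing the flag.

## What the generator does and does not emulate

The synthetic data reproduce the generative assumptions of the simulation
design exactly: i.i.d. trials, uniform parameter priors, uniform additive
delays independent of the true RT, and delays that never alter which
response was made. Real data violate several of these — sequential
dependencies, non-uniform (often bimodal, polling-locked) delay
distributions, delays correlated with system load, fast guesses and outlier
contamination. Passing tests therefore certify the machinery and the stated
conditions, not robustness of model fitting to every real-world noise
process.

## Known limitations

* The diffusion noisy-vs-clean regressions reproduce the direction of the
  published noise effect (the delay is absorbed almost entirely into
  T<sub>er</sub>, with a essentially unaffected) but not the strength of the
  published slope attenuation for T<sub>er</sub> and v. Because the noisy
  data set is the clean set plus a delay, any deterministic, well-converged
  estimator yields clean/noisy estimation errors that are almost perfectly
  correlated, forcing slopes near 1; the published attenuation implies an
  error correlation near 0.6, which points to optimizer-level stochasticity
  in the original toolbox chain that its description does not specify. The
  corresponding acceptance check is left failing rather than loosened.
* Euler simulation bias is controlled, not eliminated; halve dt to tighten.
* No trimming/censoring likelihoods, no Bayesian or quantile-probability
  ex-Gaussian estimation, no free starting point or across-trial
  variabilities in the diffusion model.
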