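# rtnoise

How much does technical timing noise — keyboard polling, OS timer granularity,
browser event latency — distort model-based analyses of reaction times (RTs)?
`rtnoise` is a simulation framework for answering that question for the two
standard RT models used in behavioural and cognitive science:

* the **ex-Gaussian distribution**, the convolution of a normal(μ, σ) and an
  exponential(mean τ) distribution, fitted by maximum likelihood;
* the **Ratcliff diffusion model** (two-boundary Wiener process) with boundary
  separation *a*, drift rate *v* and non-decision time *T*<sub>er</sub>, fitted
  under the constraints *z* = *a*/2 and η = *s*<sub>z</sub> = *s*<sub>t</sub> = 0.

The framework simulates an experiment in which the recorded RT is the true
response time plus an additive uniform delay (default U(10, 100) ms), fits the
model to the clean and the delayed version of the *same* data set, and
quantifies the systematic distortion by ordinary least squares of the
noisy-recovered on the clean-recovered parameter values across iterations: an
intercept whose 95 % CI excludes 0, or a slope whose CI excludes 1, flags a
bias. A companion pipeline measures the practical cost: attenuation of
between-condition effect sizes (paired Cohen's *d* = *t*/√n) and the extra
participants needed to keep 80 % power (smallest *n* with noncentral-*t* power
≥ .80 at two-tailed α = .05).

It is aimed at researchers who fit distributional models to RT data —
especially from browser-based experiments — and want to know which fitted
parameters they can trust under realistic timing noise.

## Worked example

Fit an ex-Gaussian to 80 simulated trials, then run a full 500-iteration
noise-recovery study:

```python
import numpy as np
from rtnoise import ExGaussParams, exgauss_rvs, exgauss_fit, run_recovery

rng = np.random.default_rng(42)
rt = exgauss_rvs(ExGaussParams(500, 50, 100), 80, rng)   # ms
res = exgauss_fit(rt)
print(res.to_row())
# {'mu': 510.072, 'sigma': 36.375, 'tau': 86.977,
#  'loglik': -464.919, 'converged': True}

study = run_recovery(model="exgauss", iterations=500, seed=11)
print(study.summary()[["intercept", "slope", "slope_ci_low", "slope_ci_high"]])
```

which prints (intercepts in ms):

```
           intercept  slope  slope_ci_low  slope_ci_high
parameter
mu            53.562  1.002         0.980          1.024
sigma         11.969  0.876         0.839          0.914
tau            0.889  0.994         0.975          1.013
```

Read: a U(10, 100) ms delay shifts the recovered μ up by roughly the mean
delay (≈ 55 ms) uniformly across its range (slope ≈ 1), inflates small σ more
than large σ (slope significantly below 1), and leaves τ essentially
untouched. The same pipeline runs for the diffusion model
(`run_recovery(model="ddm")`), where the delay is absorbed mainly into
*T*<sub>er</sub>.

Command-line equivalents: `rtnoise sim1|sim2|sim3|sim4 --seed 11 --out results/`,
plus `rtnoise fit-exgauss rt.csv` and `rtnoise fit-ddm trials.csv` for
user-supplied data.

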