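"""Ex-Gaussian reaction-time model: density, sampling and maximum-likelihood fitting.

The ex-Gaussian distribution is the convolution of a normal(mu, sigma) and an
exponential(mean tau) distribution.  It is the standard three-parameter
descriptive model for right-skewed reaction-time data: ``mu`` and ``sigma``
describe the Gaussian "core" of the distribution while ``tau`` controls the
heavy right tail.  The implied mean is ``mu + tau`` and the implied variance
``sigma**2 + tau**2``.

The model object follows the statsmodels convention: build :class:`ExGauss`
from a vector of reaction times, call :meth:`ExGauss.fit`, and read estimates
and diagnostics off the returned :class:`ExGaussResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "ExGaussParams",
    "exgauss_logpdf",
    "exgauss_pdf",
    "exgauss_loglik",
    "exgauss_rvs",
    "ExGauss",
    "ExGaussResults",
    "exgauss_fit",
    "read_rt_vector",
]

_MIN_N = 10  # below this the 3-parameter ML problem is ill-posed

# For u below this the scaled complementary error function erfcx(u/sqrt(2))
# overflows; the exponential-tail asymptote is exact to ~1e-12 there.
_TAIL_SWITCH = -25.0


@dataclass(frozen=True)
class ExGaussParams:
    """Parameter triple of the ex-Gaussian distribution, in milliseconds.

    Attributes
    ----------
    mu : float
        Mean of the normal component.
    sigma : float
        Standard deviation of the normal component.  Must be positive.
    tau : float
        Mean of the exponential component.  Must be positive.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and np.isfinite(self.sigma) and np.isfinite(self.tau)):
            raise ValueError("ex-Gaussian parameters must be finite")
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError(f"sigma and tau must be positive, got sigma={self.sigma}, tau={self.tau}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def var(self) -> float:
        return self.sigma**2 + self.tau**2

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma, self.tau])


def _as_params(params) -> ExGaussParams:
    if isinstance(params, ExGaussParams):
        return params
    return ExGaussParams(*params)


def exgauss_logpdf(x, params) -> np.ndarray:
    """Log-density of the ex-Gaussian distribution, evaluated stably.

    Uses the scaled complementary error function (``erfcx``) so that the
    ``exp((sigma/tau)**2)`` factor of the naive closed form never overflows,
    and switches to the exact exponential-tail asymptote deep in the right
    tail where ``erfcx`` itself would overflow.
    """
    p = _as_params(params)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("reaction times must be finite")
    zc = (x - p.mu) / p.sigma                       # centred normal score
    u = p.sigma / p.tau - zc                        # erfc argument (unscaled)
    out = np.empty_like(zc)
    body = u > _TAIL_SWITCH
    out[body] = (
        -np.log(2.0 * p.tau)
        - 0.5 * zc[body] ** 2
        + np.log(special.erfcx(u[body] / math.sqrt(2.0)))
    )
    # far right tail: pdf -> (1/tau) exp(sigma^2/(2 tau^2) - (x-mu)/tau)
    tail = ~body
    out[tail] = -np.log(p.tau) + 0.5 * (p.sigma / p.tau) ** 2 - (x[tail] - p.mu) / p.tau
    return out


def exgauss_pdf(x, params) -> np.ndarray:
    """Probability density of the ex-Gaussian distribution (1/ms)."""
    return np.exp(exgauss_logpdf(x, params))


def exgauss_loglik(data, params) -> float:
    """Total log-likelihood of an RT vector under an ex-Gaussian distribution."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot compute a likelihood on an empty RT vector")
    return float(np.sum(exgauss_logpdf(data, params)))


def exgauss_rvs(params, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``size`` reaction times: one normal plus one exponential draw each."""
    p = _as_params(params)
    return rng.normal(p.mu, p.sigma, size) + rng.exponential(p.tau, size)


def _moment_start(data: np.ndarray) -> np.ndarray:
    """Deterministic moment-based starting values (mu, sigma, tau)."""
    sd = data.std(ddof=1)
    tau0 = 0.8 * sd
    mu0 = data.mean() - tau0
    sigma0 = math.sqrt(max(data.var(ddof=1) - tau0**2, (0.1 * sd) ** 2))
    return np.array([mu0, sigma0, tau0])


class ExGauss:
    """Maximum-likelihood ex-Gaussian model for a single RT vector.

    Parameters
    ----------
    endog : array_like
        Reaction times in milliseconds.  At least 10 finite values with
        non-zero variance are required.

    Examples
    --------
    >>> rng = np.random.default_rng(0)
    >>> rt = exgauss_rvs(ExGaussParams(500, 50, 100), 500, rng)
    >>> res = ExGauss(rt).fit()
    >>> res.converged
    True
    """

    def __init__(self, endog) -> None:
        endog = np.asarray(endog, dtype=float).ravel()
        if endog.size < _MIN_N:
            raise ValueError(f"need at least {_MIN_N} reaction times, got {endog.size}")
        if not np.all(np.isfinite(endog)):
            raise ValueError("reaction times must be finite")
        if endog.std() == 0:
            raise ValueError("degenerate data: zero variance")
        self.endog = endog

    def loglike(self, theta: np.ndarray) -> float:
        """Log-likelihood at ``theta = (mu, log sigma, log tau)``."""
        mu, log_sigma, log_tau = theta
        params = ExGaussParams(mu, math.exp(log_sigma), math.exp(log_tau))
        return exgauss_loglik(self.endog, params)

    def fit(self, start: ExGaussParams | None = None, restart_seed: int = 0) -> "ExGaussResults":
        """Maximise the likelihood with a Nelder-Mead simplex.

        sigma and tau are log-transformed to keep them positive.  If the
        simplex fails to converge, one restart is attempted from a
        multiplicatively jittered start (+-10 %, seeded and deterministic).
        """
        if start is None:
            theta0 = _moment_start(self.endog)
        else:
            theta0 = _as_params(start).as_array()

        res = self._minimize(theta0)
        if not res.success:
            jitter = np.random.default_rng(restart_seed).uniform(0.9, 1.1, 3)
            res2 = self._minimize(theta0 * jitter)
            if res2.success or res2.fun < res.fun:
                res = res2
        mu, log_sigma, log_tau = res.x
        params = ExGaussParams(mu, math.exp(log_sigma), math.exp(log_tau))
        return ExGaussResults(
            model=self,
            params=params,
            loglik=-res.fun,
            converged=bool(res.success),
            nfev=int(res.nfev),
        )

    def _minimize(self, start_params: np.ndarray):
        theta0 = np.array([start_params[0], math.log(start_params[1]), math.log(start_params[2])])
        return optimize.minimize(
            lambda th: -self.loglike(th),
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )


@dataclass(frozen=True)
class ExGaussResults:
    """Fit results: parameter estimates, achieved log-likelihood, diagnostics."""

    model: ExGauss
    params: ExGaussParams
    loglik: float
    converged: bool
    nfev: int

    def summary(self) -> pd.DataFrame:
        p = self.params
        return pd.DataFrame(
            {
                "estimate": [p.mu, p.sigma, p.tau],
                "implied": [p.mean, math.sqrt(p.var), np.nan],
            },
            index=pd.Index(["mu", "sigma", "tau"], name="parameter"),
        ).assign(loglik=self.loglik, converged=self.converged)

    def to_row(self) -> dict:
        p = self.params
        return {
            "mu": p.mu,
            "sigma": p.sigma,
            "tau": p.tau,
            "loglik": self.loglik,
            "converged": self.converged,
        }


def exgauss_fit(data, **kwargs) -> ExGaussResults:
    """Convenience wrapper: ``ExGauss(data).fit(**kwargs)``."""
    return ExGauss(data).fit(**kwargs)


def read_rt_vector(path) -> np.ndarray:
    """Read an RT vector (ms) from a single-column CSV or whitespace-delimited file.

    Blank lines and ``#`` comments are skipped; a single non-numeric header
    line is tolerated.
    """
    values = []
    with open(path) as handle:
        for lineno, line in enumerate(handle):
            token = line.split("#", 1)[0].strip().split(",")[0].split()
            if not token:
                continue
            try:
                values.append(float(token[0]))
            except ValueError:
                if lineno == 0:  # header
                    continue
                raise ValueError(f"{path}: non-numeric value {token[0]!r} on line {lineno + 1}")
    return np.asarray(values, dtype=float)
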