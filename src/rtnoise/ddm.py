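"""Ratcliff diffusion model: trial simulation, first-passage-time density, constrained ML fit.

The model describes two-choice decisions as a Wiener process with drift ``v``
starting at ``z`` between absorbing boundaries 0 (errors) and ``a`` (correct
responses); within-trial accumulation noise has standard deviation ``s`` per
square-root second (fixed at the conventional 0.1 scaling).  Observed RT is
the first-passage (decision) time plus the non-decision time ``Ter``.

Throughout this package the starting point is constrained to the midpoint
(``z = a/2``) and the across-trial variability parameters (eta, s_z, s_t) are
fixed at zero, so only ``a``, ``v`` and ``Ter`` are free in the fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DDMParams",
    "DiffusionTrialSet",
    "ddm_simulate",
    "fpt_density",
    "fpt_cdf",
    "absorption_probability",
    "ez_starting_values",
    "WienerDiffusion",
    "WienerDiffusionResults",
    "ddm_fit",
]

#: Conventional within-trial diffusion coefficient (evidence units / sqrt s).
DEFAULT_S = 0.1

#: Broadie-Glasserman continuity-correction constant, -zeta(1/2)/sqrt(2 pi).
#: The Euler walk only inspects the path on the time grid and therefore misses
#: boundary crossings between grid points; shrinking both boundaries inward by
#: ``BETA * s * sqrt(dt)`` removes the leading-order bias this causes.
_BG_BETA = 0.5826

_TIME_CAP = 60.0  # hard cap (s) on a single simulated walk before resampling


@dataclass(frozen=True)
class DDMParams:
    """Diffusion-model parameters.

    Attributes
    ----------
    a : float
        Boundary separation (evidence units); larger values -> slower, more
        accurate responses.
    v : float
        Drift rate (evidence units per second); the mean rate of evidence
        accumulation toward the upper boundary.
    ter : float
        Non-decision time (seconds): stimulus encoding and motor execution.
    z : float
        Starting point of accumulation, constrained to ``a / 2`` here.
    s : float
        Within-trial diffusion coefficient, a fixed scaling constant.
    eta, sz, st : float
        Across-trial variabilities of v, z and Ter; fixed at zero.
    """

    a: float
    v: float
    ter: float
    z: float = None  # type: ignore[assignment]  # defaults to a/2 below
    s: float = DEFAULT_S
    eta: float = 0.0
    sz: float = 0.0
    st: float = 0.0

    def __post_init__(self) -> None:
        if self.z is None:
            object.__setattr__(self, "z", self.a / 2.0)
        if not self.a > 0:
            raise ValueError(f"boundary separation a must be positive, got {self.a}")
        if not 0 < self.z < self.a:
            raise ValueError(f"starting point z must lie strictly between 0 and a, got z={self.z}")
        if self.ter < 0:
            raise ValueError(f"non-decision time must be non-negative, got {self.ter}")
        if not self.s > 0:
            raise ValueError(f"diffusion coefficient s must be positive, got {self.s}")
        if self.eta or self.sz or self.st:
            raise ValueError("across-trial variability parameters are fixed at zero in this package")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.v, self.ter])


@dataclass
class DiffusionTrialSet:
    """A set of two-choice trials: total RTs (seconds) and boundary labels.

    ``response`` is 1 for upper-boundary (correct) and 0 for lower-boundary
    (error) responses.  ``n_resampled`` counts simulated walks that hit the
    hard time cap and were redrawn.
    """

    rt: np.ndarray
    response: np.ndarray
    n_resampled: int = 0

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float).ravel()
        self.response = np.asarray(self.response, dtype=int).ravel()
        if self.rt.shape != self.response.shape:
            raise ValueError("rt and response must have the same length")
        if np.any(self.rt <= 0):
            raise ValueError("all reaction times must be positive")
        if not np.all(np.isin(self.response, (0, 1))):
            raise ValueError("responses must be 0 (lower) or 1 (upper)")

    def __len__(self) -> int:
        return self.rt.size

    def with_rt(self, rt: np.ndarray) -> "DiffusionTrialSet":
        """Copy with replaced RTs; responses are untouched (delays do not flip choices)."""
        return DiffusionTrialSet(rt, self.response.copy(), self.n_resampled)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rt_seconds": self.rt, "response": self.response})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiffusionTrialSet":
        frame = pd.read_csv(path)
        return cls(frame["rt_seconds"].to_numpy(), frame["response"].to_numpy())


def ddm_simulate(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = 5e-4,
    continuity_correction: bool = True,
) -> DiffusionTrialSet:
    """Simulate ``n`` diffusion trials by an Euler-Maruyama walk.

    Each trial starts at ``z`` and takes increments ``v*dt + s*sqrt(dt)*N(0,1)``
    until it crosses 0 or ``a``; the recorded RT is the crossing time plus
    ``ter``.  With ``continuity_correction`` both boundaries are shrunk inward
    by ``0.5826 * s * sqrt(dt)`` to cancel the discrete-inspection bias of the
    Euler scheme.  Walks that survive 60 s are redrawn (and counted).
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.005:
        warnings.warn(f"dt={dt} s is coarse for a diffusion walk; consider dt <= 5e-4", stacklevel=2)

    shift = _BG_BETA * params.s * math.sqrt(dt) if continuity_correction else 0.0
    upper, lower = params.a - shift, shift
    sq = params.s * math.sqrt(dt)
    max_steps = int(_TIME_CAP / dt)

    rt = np.empty(n)
    resp = np.empty(n, dtype=int)
    n_resampled = 0
    todo = np.arange(n)
    while todo.size:
        x = np.full(todo.size, params.z)
        alive = np.arange(todo.size)
        done_time = np.full(todo.size, np.nan)
        done_up = np.zeros(todo.size, dtype=bool)
        for step in range(1, max_steps + 1):
            x[alive] += params.v * dt + sq * rng.standard_normal(alive.size)
            hit_up = x[alive] >= upper
            hit_lo = x[alive] <= lower
            done = hit_up | hit_lo
            if done.any():
                idx = alive[done]
                done_time[idx] = step * dt
                done_up[idx] = hit_up[done]
                alive = alive[~done]
            if alive.size == 0:
                break
        finished = np.isfinite(done_time)
        rt[todo[finished]] = done_time[finished] + params.ter
        resp[todo[finished]] = done_up[finished].astype(int)
        n_resampled += int((~finished).sum())
        todo = todo[~finished]
    return DiffusionTrialSet(rt, resp, n_resampled=n_resampled)


def absorption_probability(params: DDMParams, boundary: str = "upper") -> float:
    """Closed-form probability of absorption at a boundary (no time dimension)."""
    a, v, z, s = params.a, params.v, params.z, params.s
    if v == 0:
        p_up = z / a
    else:
        k = 2.0 * v / s**2
        p_up = -math.expm1(-k * z) / -math.expm1(-k * a)
    return p_up if boundary == "upper" else 1.0 - p_up


def _fpt_lower_unit(t: np.ndarray, v: float, a: float, w: float, eps: float) -> np.ndarray:
    """Defective FPT density at the lower boundary in unit-diffusion scaling.

    Evaluates the classical image-sum (small-time) or eigenfunction
    (large-time) series, choosing per time point whichever needs fewer terms
    for absolute truncation error below ``eps``.
    """
    tt = t / a**2  # boundary-normalised time
    f = np.zeros_like(tt)
    pos = tt > 0
    ttp = tt[pos]
    with np.errstate(invalid="ignore"):
        n_small = 2.0 + np.sqrt(
            np.maximum(-2.0 * ttp * np.log(np.maximum(2.0 * eps * np.sqrt(2.0 * np.pi * ttp), 1e-300)), 0.0)
        )
        n_large = np.sqrt(
            np.maximum(-2.0 * np.log(np.maximum(np.pi * ttp * eps, 1e-300)) / (np.pi**2 * ttp), 0.0)
        )
        n_large = np.maximum(n_large, 1.0 / (np.pi * np.sqrt(ttp)))
    use_small = n_small < n_large

    body = np.zeros_like(ttp)
    if use_small.any():
        ts = ttp[use_small]
        k_max = int(math.ceil(n_small[use_small].max()))
        acc = np.zeros_like(ts)
        for k in range(-((k_max - 1) // 2), (k_max + 1) // 2 + 1):
            q = w + 2.0 * k
            acc += q * np.exp(-(q * q) / (2.0 * ts))
        body[use_small] = acc / np.sqrt(2.0 * np.pi * ts**3)
    if (~use_small).any():
        tl = ttp[~use_small]
        k_max = int(math.ceil(n_large[~use_small].max()))
        acc = np.zeros_like(tl)
        for k in range(1, k_max + 1):
            acc += k * np.exp(-(k * k) * (np.pi**2) * tl / 2.0) * math.sin(k * np.pi * w)
        body[~use_small] = acc * np.pi
    f[pos] = np.maximum(body, 0.0) * np.exp(-v * a * w - (v**2) * t[pos] / 2.0) / a**2
    return f


def fpt_density(t, params: DDMParams, boundary: str = "upper", eps: float = 1e-10) -> np.ndarray:
    """Defective first-passage-time density (1/s) at one boundary.

    ``t`` is decision time (RT minus ``ter``).  The two defective densities
    jointly integrate to 1.  Non-positive ``t`` returns density 0 by
    convention; likelihood-level handling of observed ``rt <= ter`` lives in
    :class:`WienerDiffusion`.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    v_unit, a_unit, w = params.v / params.s, params.a / params.s, params.z / params.a
    if boundary == "lower":
        return _fpt_lower_unit(t, v_unit, a_unit, w, eps)
    return _fpt_lower_unit(t, -v_unit, a_unit, 1.0 - w, eps)


def _defective_cdf_lower_unit(t: np.ndarray, v: float, a: float, w: float, eps: float) -> tuple:
    """Defective FPT CDF at the lower boundary in unit-diffusion scaling.

    Integrates the large-time eigenfunction series term by term in closed
    form: each mode decays as ``exp(-lambda_k t)``, so the tail sum converges
    geometrically for any t > 0.  Returns ``(cdf values, total mass)``.
    """
    if v == 0:
        mass = 1.0 - w
    else:
        mass = 1.0 + math.expm1(-2.0 * v * a * w) / -math.expm1(-2.0 * v * a)
    out = np.zeros_like(t)
    pos = t > 0
    if pos.any():
        tp = t[pos]
        t_min = float(tp.min())
        # number of modes for truncation error < eps at the smallest t
        k_max = int(min(max(10, math.ceil(a / math.pi * math.sqrt(2.0 * math.log(1.0 / eps) / t_min))), 1000))
        k = np.arange(1, k_max + 1)[:, None]
        lam = (v**2 + (k * np.pi / a) ** 2) / 2.0
        tail = (np.pi / a**2) * math.exp(-v * a * w) * (
            (k * np.sin(k * np.pi * w) / lam) * np.exp(-lam * tp[None, :])
        ).sum(axis=0)
        out[pos] = np.clip(mass - tail, 0.0, mass)
    return out, mass


def fpt_cdf(t, params: DDMParams, boundary: str = "upper", eps: float = 1e-12) -> np.ndarray:
    """Defective first-passage-time CDF: P(absorbed at ``boundary`` by decision time t)."""
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    v_unit, a_unit, w = params.v / params.s, params.a / params.s, params.z / params.a
    if boundary == "lower":
        return _defective_cdf_lower_unit(t, v_unit, a_unit, w, eps)[0]
    return _defective_cdf_lower_unit(t, -v_unit, a_unit, 1.0 - w, eps)[0]


def ez_starting_values(rt: np.ndarray, response: np.ndarray, s: float = DEFAULT_S) -> np.ndarray:
    """Moment-based starting values (a, v, Ter) from the EZ-diffusion closed forms.

    Uses accuracy, correct-RT mean and variance; accuracy is edge-corrected
    away from 0, 1/2 and 1.  Falls back to a generic start if the data are
    too sparse for the formulas.
    """
    n = rt.size
    pc = float(response.mean())
    pc = min(max(pc, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
    if abs(pc - 0.5) < 1.0 / (2 * n):
        pc = 0.5 + 1.0 / (2 * n)
    correct = rt[response == 1]
    if correct.size < 5:
        correct = rt
    vrt = float(correct.var(ddof=1))
    if vrt <= 0:
        return np.array([0.2, 0.2, 0.9 * float(rt.min())])
    mrt = float(correct.mean())
    logit = math.log(pc / (1.0 - pc))
    x = logit * (logit * pc**2 - logit * pc + pc - 0.5) / vrt
    v0 = math.copysign(1.0, pc - 0.5) * s * abs(x) ** 0.25
    a0 = s**2 * logit / v0
    y = -v0 * a0 / s**2
    mdt = (a0 / (2.0 * v0)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    ter0 = max(mrt - mdt, 1e-3)
    return np.array([min(max(a0, 0.05), 0.6), min(max(v0, 0.02), 0.6), ter0])


class WienerDiffusion:
    """Constrained diffusion model for one trial set.

    Only ``a``, ``v`` and ``Ter`` are free; the starting point is pinned to
    the midpoint (z = a/2) and across-trial variabilities to zero.  Two
    objectives are available:

    ``method="quantile"`` (default)
        Multinomial likelihood of the counts falling between the observed RT
        quantiles (.1, .3, .5, .7, .9) at each boundary, with expected bin
        probabilities from the defective FPT CDF.  This is the objective
        class used by the standard diffusion-fitting toolboxes and is the
        default for the recovery pipelines.
    ``method="continuous"``
        Continuous likelihood of each trial's (RT, response) pair under the
        defective first-passage densities.
    """

    #: penalty slope for trials with rt <= Ter during the search (smooth
    #: repulsion instead of a -inf cliff, keeps the simplex stable)
    _PENALTY = 1e6
    _PENALTY_EPS = 1e-4

    #: outer quantiles used to bin each boundary's RTs (toolbox convention)
    _QPROBS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    _QWEIGHTS = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.1])
    #: boundaries with fewer responses than this are reduced to a median
    #: split (or total mass only, below _MIN_ANY) instead of 5 quantiles
    _MIN_FULL = 10
    _MIN_ANY = 4

    def __init__(self, data: DiffusionTrialSet, s: float = DEFAULT_S) -> None:
        self.data = data
        self.s = s
        self.n_upper = int(data.response.sum())
        self.n_lower = len(data) - self.n_upper
        self.low_information = len(data) < 50 or self.n_upper == 0 or self.n_lower == 0

    def loglike(self, theta: np.ndarray) -> float:
        """Continuous penalised log-likelihood at ``theta = (a, v, ter)``."""
        a, v, ter = theta
        if a <= 0 or ter < 0:
            return -1e12
        params = DDMParams(a=a, v=v, ter=ter, s=self.s)
        rt, resp = self.data.rt, self.data.response
        dec = rt - ter
        ok = dec > 0
        total = -self._PENALTY * np.sum(ter - rt[~ok] + self._PENALTY_EPS)
        for label, name in ((1, "upper"), (0, "lower")):
            m = ok & (resp == label)
            if m.any():
                dens = fpt_density(dec[m], params, boundary=name)
                total += float(np.sum(np.log(np.maximum(dens, 1e-300))))
        return float(total)

    def loglike_quantile(self, theta: np.ndarray) -> float:
        """Quantile-multinomial log-likelihood at ``theta = (a, v, ter)``."""
        a, v, ter = theta
        if a <= 0.01 or ter < 0:
            return -1e12
        params = DDMParams(a=a, v=v, ter=ter, s=self.s)
        rt, resp = self.data.rt, self.data.response
        total = 0.0
        for label, name in ((1, "upper"), (0, "lower")):
            r = rt[resp == label]
            n_b = r.size
            if n_b == 0:
                continue
            if n_b < self._MIN_ANY:
                mass = absorption_probability(params, name)
                total += n_b * math.log(max(mass, 1e-12))
                continue
            if n_b < self._MIN_FULL:
                q = np.quantile(r, [0.5])
                weights = np.array([0.5, 0.5])
            else:
                q = np.quantile(r, self._QPROBS)
                weights = self._QWEIGHTS
            cdf = fpt_cdf(q - ter, params, boundary=name)
            mass = absorption_probability(params, name)
            probs = np.diff(np.concatenate(([0.0], cdf, [mass])))
            total += float(np.sum(weights * n_b * np.log(np.maximum(probs, 1e-12))))
        return float(total)

    def fit(
        self,
        start: np.ndarray | None = None,
        method: str = "quantile",
        restart_seed: int = 0,
    ) -> "WienerDiffusionResults":
        """Maximise the chosen objective with Nelder-Mead.

        The start defaults to the EZ-diffusion moment estimates computed from
        the data.  One seeded jittered restart (+-10 % multiplicative) is
        attempted if the simplex fails to converge.
        """
        if method not in ("quantile", "continuous"):
            raise ValueError(f"unknown fit method {method!r}")
        objective = self.loglike_quantile if method == "quantile" else self.loglike
        if start is None:
            start = ez_starting_values(self.data.rt, self.data.response, self.s)
        start = np.asarray(start, dtype=float)
        res = self._minimize(objective, start)
        if not res.success:
            jitter = np.random.default_rng(restart_seed).uniform(0.9, 1.1, 3)
            res2 = self._minimize(objective, start * jitter)
            if res2.success or res2.fun < res.fun:
                res = res2
        a, v, ter = res.x
        params = DDMParams(a=a, v=v, ter=max(ter, 0.0), s=self.s)
        return WienerDiffusionResults(
            model=self,
            params=params,
            loglik=-res.fun,
            converged=bool(res.success),
            nfev=int(res.nfev),
            method=method,
            low_information=self.low_information,
        )

    def _minimize(self, objective, theta0: np.ndarray):
        return optimize.minimize(
            lambda th: -objective(th),
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )


@dataclass(frozen=True)
class WienerDiffusionResults:
    """Constrained diffusion fit: estimates of (a, v, Ter) plus diagnostics."""

    model: WienerDiffusion
    params: DDMParams
    loglik: float
    converged: bool
    nfev: int
    method: str = "quantile"
    low_information: bool = False

    def summary(self) -> pd.DataFrame:
        p = self.params
        return pd.DataFrame(
            {"estimate": [p.a, p.v, p.ter]},
            index=pd.Index(["a", "v", "Ter"], name="parameter"),
        ).assign(loglik=self.loglik, converged=self.converged)

    def to_row(self) -> dict:
        p = self.params
        return {"a": p.a, "v": p.v, "ter": p.ter, "loglik": self.loglik, "converged": self.converged}


def ddm_fit(data: DiffusionTrialSet, **kwargs) -> WienerDiffusionResults:
    """Convenience wrapper: ``WienerDiffusion(data).fit(**kwargs)``."""
    return WienerDiffusion(data).fit(**kwargs)
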