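"""Generative machinery for the noise-robustness simulations.

Emulates the study conditions: per-iteration parameters drawn from uniform
priors, RT vectors sampled from the generating model, and an additive
technical-noise model -- an independent uniform delay (default U(10, 100) ms)
added to every recorded RT, standing in for keyboard polling, OS timer
granularity and browser timing overhead.  The noisy data set is always the
clean data set plus noise, never an independent redraw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddm import DDMParams, DiffusionTrialSet
from .exgauss import ExGaussParams, exgauss_rvs

__all__ = [
    "PriorSpec",
    "NoiseSpec",
    "sample_params",
    "generate_exgauss_trials",
    "add_noise",
    "add_noise_diffusion",
    "substreams",
    "EXGAUSS_PRIOR",
    "DDM_PRIOR",
    "DEFAULT_NOISE",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform bounds per parameter, in each parameter's native units.

    ``kind`` selects the model whose parameters are drawn ('exgauss' draws
    (mu, sigma, tau) in ms; 'ddm' draws (a, v, ter) and pins z = a/2).
    """

    kind: str
    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.kind not in ("exgauss", "ddm"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        for name, (low, high) in self.bounds.items():
            if not low <= high:
                raise ValueError(f"prior for {name}: low={low} exceeds high={high}")


#: Study priors: mu ~ U(450, 550), sigma ~ U(25, 75), tau ~ U(50, 150) ms.
EXGAUSS_PRIOR = PriorSpec("exgauss", {"mu": (450.0, 550.0), "sigma": (25.0, 75.0), "tau": (50.0, 150.0)})

#: Study priors: a, v, Ter each ~ U(0.15, 0.25) on the s = 0.1 scale.
DDM_PRIOR = PriorSpec("ddm", {"a": (0.15, 0.25), "v": (0.15, 0.25), "ter": (0.15, 0.25)})


@dataclass(frozen=True)
class NoiseSpec:
    """Additive uniform technical delay, bounds in milliseconds."""

    low: float = 10.0
    high: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.low <= self.high:
            raise ValueError(f"need 0 <= low <= high, got ({self.low}, {self.high})")

    @property
    def is_null(self) -> bool:
        return self.low == 0.0 and self.high == 0.0

    def draw_ms(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.low == self.high:
            return np.full(n, self.low)
        return rng.uniform(self.low, self.high, n)


#: The default technical-noise model: U(10, 100) ms per recorded RT.
DEFAULT_NOISE = NoiseSpec(10.0, 100.0)


def sample_params(prior: PriorSpec, rng: np.random.Generator):
    """Draw one parameter set from the prior.

    Returns :class:`ExGaussParams` or :class:`DDMParams` according to
    ``prior.kind``; diffusion draws impose z = a/2 exactly.
    """
    draws = {}
    for name, (low, high) in prior.bounds.items():
        draws[name] = low if low == high else rng.uniform(low, high)
    if prior.kind == "exgauss":
        return ExGaussParams(**draws)
    return DDMParams(a=draws["a"], v=draws["v"], ter=draws["ter"])


def generate_exgauss_trials(params: ExGaussParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` ex-Gaussian RTs (ms): a normal draw plus an exponential draw each."""
    if n < 1:
        raise ValueError("need at least one trial")
    return exgauss_rvs(params, n, rng)


def add_noise(trials: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Add an independent uniform delay (ms) to each RT; order and length preserved."""
    trials = np.asarray(trials, dtype=float)
    return trials + noise.draw_ms(trials.size, rng)


def add_noise_diffusion(
    trials: DiffusionTrialSet, noise: NoiseSpec, rng: np.random.Generator
) -> DiffusionTrialSet:
    """Add the same uniform technical delay to diffusion RTs, converted to seconds.

    The delay perturbs the recorded timestamp only; response labels never change.
    """
    delay_s = noise.draw_ms(len(trials), rng) / 1000.0
    return trials.with_rt(trials.rt + delay_s)


def substreams(seed, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent child generators from a master seed.

    Accepts an int or an existing :class:`numpy.random.SeedSequence`, so whole
    pipelines can be driven from one top-level seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
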