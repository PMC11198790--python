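"""Lévy flights: heavy-tailed step sampling and the position-update operator.

The closed-form density implemented here is the one-sided Lévy law

    L(s; gamma, mu) = sqrt(gamma / (2 pi)) * exp(-gamma / (2 (s - mu)))
                      * (s - mu)^(-3/2),     s > mu,

whose far tail falls off like ``s^(-3/2)``.  Step *sampling* for general
stability index ``beta`` in (0, 2] uses Mantegna's algorithm: the ratio
``u / |v|^(1/beta)`` of two Gaussians with the variance of ``u`` chosen so
the ratio's magnitude has survival-function exponent ``beta``.  Rare long
jumps from the power-law tail are what give Lévy flights their global
exploration ability inside the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from baoscnn.search_space import SearchSpace

__all__ = [
    "LevyConfig",
    "levy_density",
    "sample_steps",
    "levy_displacement",
    "levy_move",
    "fit_tail_index",
]

# Raw steps are clipped at this many dimension spans (after scaling) so a
# single extreme tail draw cannot overflow downstream arithmetic.
_CLIP_SPANS = 100.0


@dataclass(frozen=True)
class LevyConfig:
    """Parameters of the Lévy operator.

    ``beta`` is the stability index in (0, 2] (1.5 by default, the usual
    choice in Lévy-flight metaheuristics); ``gamma``/``mu`` parameterise the
    closed-form density; ``step_scale`` multiplies the per-dimension span to
    set the raw jump length scale.
    """

    beta: float = 1.5
    gamma: float = 1.0
    mu: float = 0.0
    step_scale: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 2.0:
            raise ValueError("beta must be in (0, 2]")
        if self.gamma <= 0.0:
            raise ValueError("gamma must be > 0")
        if self.step_scale <= 0.0:
            raise ValueError("step_scale must be > 0")


def levy_density(s, gamma: float = 1.0, mu: float = 0.0):
    """Closed-form one-sided Lévy density; 0 at and below the minimum step ``mu``."""
    if gamma <= 0.0:
        raise ValueError("gamma must be > 0")
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    sup = s > mu
    x = s[sup] - mu
    out[sup] = math.sqrt(gamma / (2.0 * math.pi)) * np.exp(-gamma / (2.0 * x)) * x ** -1.5
    if out.ndim == 0:
        return float(out)
    return out


def _mantegna_sigma(beta: float) -> float:
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def sample_steps(count: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` heavy-tailed Lévy steps via Mantegna's algorithm.

    The survival function of ``|step|`` has power-law exponent ~ ``beta``.
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must be in (0, 2]")
    if count < 1:
        raise ValueError("count must be >= 1")
    sigma = _mantegna_sigma(beta)
    u = rng.normal(0.0, sigma, size=count)
    v = rng.normal(0.0, 1.0, size=count)
    return u / np.abs(v) ** (1.0 / beta)


def fit_tail_index(steps: np.ndarray) -> float:
    """Estimate the power-law exponent of the step-magnitude survival
    function by log-log regression over the top decade of magnitudes.

    The decade ends at the 99.9th percentile (order-statistic noise above
    it); for a survival function ~ s^-beta the fitted slope recovers beta.
    """
    mags = np.sort(np.abs(np.asarray(steps, dtype=float)))
    hi = np.quantile(mags, 0.999)
    lo = hi / 10.0
    n = mags.size
    sf = 1.0 - (np.arange(1, n + 1) - 0.5) / n  # empirical survival at sorted mags
    sel = (mags >= lo) & (mags <= hi) & (sf > 0)
    slope, _ = np.polyfit(np.log(mags[sel]), np.log(sf[sel]), 1)
    return float(-slope)


def levy_displacement(
    space: SearchSpace,
    config: LevyConfig,
    rng: np.random.Generator,
    scale: np.ndarray | None = None,
) -> np.ndarray:
    """Pre-repair displacement vector: ``rand(d) * Levy(beta) * scale``.

    The per-dimension ``scale`` defaults to ``step_scale * span``; callers
    may pass an adaptive scale vector instead (the optimizer's stagnation
    restarts scale by distance from the best-so-far).  The uniform vector
    and the Lévy steps are drawn entry-wise, so the per-dimension
    displacements are independent; the result is clipped at ``100 * span``
    per dimension.
    """
    d = space.d
    span = space.span
    if scale is None:
        scale = config.step_scale * span
    r = rng.random(d)
    steps = sample_steps(d, config.beta, rng)
    disp = r * steps * scale
    limit = _CLIP_SPANS * span
    return np.clip(disp, -limit, limit)


def levy_move(
    position: np.ndarray,
    space: SearchSpace,
    config: LevyConfig,
    rng: np.random.Generator,
    scale: np.ndarray | None = None,
) -> np.ndarray:
    """One Lévy-flight jump from ``position``, repaired into the space."""
    return space.repair(
        np.asarray(position, dtype=float) + levy_displacement(space, config, rng, scale)
    )
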