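"""Replication probability, power, and sample-size planning.

An exact replication of a study with signal-to-noise ratio SNR produces
z_repl ~ N(sqrt(m) * SNR, 1) when the replication sample size is m times the
original (the SNR scales with the square root of the sample size).  A
replication is successful when it is significant in the same direction as
the original:

    z * z_repl > 0  and  |z_repl| > c,       c = Phi^{-1}(1 - alpha/2).

Given the fitted z mixture, the posterior of SNR given z is itself a normal
mixture, so the conditional replication probability has a closed form:

    P(success | z) = sum_k pi_k(z) * [1 - Phi((c - sqrt(m) mu_k) / sqrt(m v_k + 1))]

for z > 0 (mirror image for z < 0).  Power is the related unconditional
functional of SNR: Phi(-c - SNR) + 1 - Phi(c - SNR), which includes
wrong-direction rejections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigError, EmptyResultError, UnattainableError, ValidationError
from .mixture import SNRMixture, ZMixture

__all__ = [
    "ReplicationQuery",
    "ReplicationCurve",
    "PowerDistribution",
    "significance_threshold",
    "replication_probability",
    "replication_curve",
    "power_of_snr",
    "invert_power",
    "power_distribution",
    "average_replicability",
    "required_sample_factor",
]


def significance_threshold(alpha: float = 0.05) -> float:
    """Two-sided critical value c = Phi^{-1}(1 - alpha/2) (1.959964... at 0.05)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0,1)")
    return float(norm.isf(alpha / 2.0))


@dataclass(frozen=True)
class ReplicationQuery:
    """An original study's z statistic and the replication design."""

    z_obs: float
    m: float = 1.0
    alpha: float = 0.05
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ConfigError("fold-increase m must be > 0")
        object.__setattr__(self, "threshold", significance_threshold(self.alpha))


@dataclass(frozen=True)
class ReplicationCurve:
    z_grid: np.ndarray
    point: np.ndarray
    m: float


@dataclass(frozen=True)
class PowerDistribution:
    """CDF of statistical power implied by an SNR mixture."""

    p_grid: np.ndarray
    cdf: np.ndarray
    quantiles: dict[float, float]
    alpha: float


def _rep_prob_components(sigmas: np.ndarray, z_abs, m: float,
                         c: float) -> np.ndarray:
    """Per-component success probability 1 - Phi((c - sqrt(m) mu_k)/sqrt(m v_k + 1)).

    ``z_abs`` may be scalar or an array broadcast against the component axis
    (last axis).  Valid for z_abs >= 0; at z_abs = 0 returns the upper-tail
    probability only (callers handle the direction-free case).
    """
    s2 = sigmas**2
    shrink = (s2 - 1.0) / s2
    z_abs = np.asarray(z_abs, dtype=float)[..., None]
    mu = z_abs * shrink
    sd = np.sqrt(m * shrink + 1.0)
    return norm.sf((c - np.sqrt(m) * mu) / sd)


def _posterior_weights(mix: ZMixture, z_abs) -> np.ndarray:
    from scipy.special import logsumexp

    z_abs = np.asarray(z_abs, dtype=float)[..., None]
    lp = (np.log(np.maximum(mix.weights, 1e-300)) - np.log(mix.sigmas)
          - 0.5 * z_abs**2 / mix.sigmas**2)
    return np.exp(lp - logsumexp(lp, axis=-1, keepdims=True))


def _rep_prob(mix: ZMixture, z, m: float, alpha: float) -> np.ndarray:
    """Vectorized replication probability over z (same-sign significance)."""
    c = significance_threshold(alpha)
    z = np.asarray(z, dtype=float)
    z_abs = np.abs(z)
    pi = _posterior_weights(mix, z_abs)
    p_same = np.sum(pi * _rep_prob_components(mix.sigmas, z_abs, m, c), axis=-1)
    # z = 0: the direction is ill-posed; report significance in either tail
    if np.any(z_abs == 0):
        s2 = mix.sigmas**2
        sd = np.sqrt(m * (s2 - 1.0) / s2 + 1.0)
        p_sig0 = float((_posterior_weights(mix, 0.0)
                        * 2.0 * norm.sf(c / sd)).sum())
        p_same = np.where(z_abs == 0, p_sig0, p_same)
    return p_same


def replication_probability(mix: ZMixture, query: ReplicationQuery | float,
                            m: float = 1.0, alpha: float = 0.05) -> float:
    """Conditional probability of a successful exact replication given z.

    ``query`` may be a :class:`ReplicationQuery` or a bare z value (then
    ``m`` and ``alpha`` apply).  Symmetric in z.  At z = 0 the direction
    requirement is ill-posed; the significance-only probability is returned
    with a warning.
    """
    if not isinstance(query, ReplicationQuery):
        query = ReplicationQuery(z_obs=float(query), m=m, alpha=alpha)
    if query.z_obs == 0.0:
        warnings.warn("z = 0: direction undefined; returning significance-only "
                      "probability", stacklevel=2)
    return float(_rep_prob(mix, query.z_obs, query.m, query.alpha))


def replication_curve(mix: ZMixture, z_grid, m: float = 1.0,
                      alpha: float = 0.05) -> ReplicationCurve:
    """Element-wise replication probability over a z grid."""
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.size == 0:
        raise ValidationError("empty z grid")
    if np.any(np.diff(z_grid) < 0):
        raise ValidationError("z grid must be sorted")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pts = _rep_prob(mix, z_grid, m, alpha)
    return ReplicationCurve(z_grid=z_grid, point=pts, m=m)


def power_of_snr(snr, alpha: float = 0.05) -> np.ndarray | float:
    """Two-sided rejection probability Phi(-c - SNR) + 1 - Phi(c - SNR).

    Includes significance in the wrong direction; equals alpha at SNR = 0.
    """
    c = significance_threshold(alpha)
    snr = np.asarray(snr, dtype=float)
    out = norm.cdf(-c - snr) + norm.sf(c - snr)
    return float(out) if out.ndim == 0 else out


def invert_power(p: float, alpha: float = 0.05) -> float:
    """|SNR| at which power equals p (bisection; power is increasing in |SNR|)."""
    if not alpha < p < 1.0:
        raise ConfigError(f"power must lie in ({alpha}, 1)")
    return float(brentq(lambda x: power_of_snr(x, alpha) - p, 0.0, 50.0,
                        xtol=1e-10))


def power_distribution(snr_mix: SNRMixture, p_grid=None, quantiles=(0.25, 0.5, 0.75),
                       alpha: float = 0.05) -> PowerDistribution:
    """Distribution of power implied by the SNR mixture.

    Uses the monotonicity of power in |SNR|:
    P(power <= p) = P(|SNR| <= snr(p)), and the q-quantile of power is the
    power at the q-quantile of |SNR|.
    """
    if p_grid is None:
        p_grid = np.linspace(alpha + 1e-6, 1.0 - 1e-9, 200)
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any(p_grid <= alpha) or np.any(p_grid >= 1.0):
        raise ConfigError(f"power grid values must lie in ({alpha}, 1)")
    cdf = np.array([float(snr_mix.abs_cdf(invert_power(p, alpha)))
                    for p in p_grid])
    qs = {float(q): float(power_of_snr(snr_mix.abs_quantile(q), alpha))
          for q in quantiles}
    return PowerDistribution(p_grid=p_grid, cdf=cdf, quantiles=qs, alpha=alpha)


def average_replicability(mix: ZMixture, z_values, weights=None, *,
                          m: float = 1.0, alpha: float = 0.05,
                          condition: str = "significant") -> float:
    """Weighted mean replication probability over observed z meeting a condition.

    ``condition='significant'`` restricts to |z| > c (the default, matching
    the usual "among statistically significant effects" summary);
    ``condition='all'`` averages over every observation.  Weights are
    renormalized over the conditioned subset.
    """
    z = np.asarray(z_values, dtype=float)
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if condition == "significant":
        mask = np.abs(z) > significance_threshold(alpha)
    elif condition == "all":
        mask = np.ones_like(z, dtype=bool)
    else:
        raise ConfigError(f"unknown condition {condition!r}")
    if not mask.any():
        raise EmptyResultError("no observations satisfy the condition")
    z, w = z[mask], w[mask]
    probs = _rep_prob(mix, z, m, alpha)
    return float(np.average(probs, weights=w))


def required_sample_factor(mix: ZMixture, z_obs: float, target: float,
                           alpha: float = 0.05, *, m_lo: float = 1e-6,
                           m_hi: float = 1e4, prob_tol: float = 1e-4) -> float:
    """Smallest fold-increase m with replication probability >= target.

    Bisection on log m over [m_lo, m_hi]; the probability is increasing in m
    for z != 0.  Returns a continuous m (callers may ceil for presentation).
    Raises :class:`UnattainableError` when even m_hi falls short, reporting
    the estimated supremum.
    """
    if not alpha / 2.0 < target < 1.0:
        raise ConfigError(f"target must be in ({alpha / 2.0}, 1)")
    if z_obs == 0.0:
        raise ConfigError("z = 0: replication direction undefined")

    def prob(m: float) -> float:
        return float(_rep_prob(mix, z_obs, m, alpha))

    if prob(m_lo) >= target:
        return m_lo
    p_hi = prob(m_hi)
    if p_hi < target:
        raise UnattainableError(
            f"target {target} unattainable: probability at m={m_hi:g} is "
            f"{p_hi:.6f}", supremum=p_hi)
    lo, hi = np.log(m_lo), np.log(m_hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p_mid = prob(np.exp(mid))
        if p_mid >= target:
            hi = mid
            if p_mid - target < prob_tol and hi - lo < 1e-6:
                break
        else:
            lo = mid
        if hi - lo < 1e-12:
            break
    return float(np.exp(hi))
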