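"""Zero-mean Gaussian scale mixtures for z statistics and their SNR deconvolution.

The marginal density of the z statistics is modelled as

    f(z) = sum_k w_k phi(z / sigma_k) / sigma_k,        sigma_k >= 1,

fitted by weighted maximum likelihood (EM) with per-effect cluster weights.
Because z | SNR ~ N(SNR, 1), the signal-to-noise-ratio distribution follows by
deconvolution: a scale mixture with the same weights and tau_k = sqrt(sigma_k^2 - 1).
The conditional (posterior) law of SNR given z is available in closed form:
given component k, SNR | z ~ N(z tau_k^2/sigma_k^2, tau_k^2/sigma_k^2), with
component probabilities proportional to w_k phi(z/sigma_k)/sigma_k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import ConfigError, ValidationError

__all__ = [
    "ZMixture",
    "SNRMixture",
    "PosteriorSNR",
    "FitReport",
    "fit_z_mixture",
    "fit_table",
    "deconvolve",
    "reconvolve",
    "z_density",
    "posterior_snr",
    "save_model",
    "load_model",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ZMixture:
    """Zero-mean normal scale mixture for the marginal of z.

    weights sum to 1; sigmas are >= 1 and strictly increasing.
    """

    weights: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        s = np.asarray(self.sigmas, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "sigmas", s)
        if w.shape != s.shape or w.ndim != 1 or w.size == 0:
            raise ValidationError("weights and sigmas must be matching 1-d arrays")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(s))):
            raise ValidationError("non-finite mixture parameters")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValidationError("weights must be non-negative and sum to 1")
        if np.any(s < 1.0 - 1e-12):
            raise ValidationError("sigma components must be >= 1")

    @property
    def K(self) -> int:
        return int(self.weights.size)

    def logpdf(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        lp = (np.log(np.maximum(self.weights, 1e-300)) - np.log(self.sigmas)
              - _LOG_SQRT_2PI
              - 0.5 * (z[..., None] / self.sigmas) ** 2)
        return logsumexp(lp, axis=-1)

    def pdf(self, z) -> np.ndarray:
        return np.exp(self.logpdf(z))

    def cdf(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return norm.cdf(z[..., None] / self.sigmas) @ self.weights

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "sigmas": self.sigmas.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ZMixture":
        return cls(np.asarray(d["weights"]), np.asarray(d["sigmas"]))


@dataclass(frozen=True)
class SNRMixture:
    """Deconvolved zero-mean scale mixture for the SNR; tau_k = sqrt(sigma_k^2 - 1)."""

    weights: np.ndarray
    taus: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.taus, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "taus", t)
        if np.any(t < 0):
            raise ValidationError("tau components must be >= 0")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValidationError("weights must be non-negative and sum to 1")

    @property
    def K(self) -> int:
        return int(self.weights.size)

    def pdf(self, snr) -> np.ndarray:
        """Density of SNR; components with tau=0 are point masses at 0 and
        contribute no absolutely-continuous density."""
        snr = np.asarray(snr, dtype=float)
        out = np.zeros(np.broadcast(snr, 0.0).shape)
        for w, t in zip(self.weights, self.taus):
            if t > 0:
                out = out + w * norm.pdf(snr / t) / t
        return out

    def abs_cdf(self, x) -> np.ndarray:
        """P(|SNR| <= x) for x >= 0 (tau=0 components count fully)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros(np.broadcast(x, 0.0).shape)
        for w, t in zip(self.weights, self.taus):
            if t > 0:
                out = out + w * (2.0 * norm.cdf(x / t) - 1.0)
            else:
                out = out + w * (x >= 0)
        return out

    def abs_quantile(self, q: float) -> float:
        """Generalized inverse of the |SNR| CDF."""
        from scipy.optimize import brentq

        if not 0.0 < q < 1.0:
            raise ValidationError("quantile level must be in (0,1)")
        if self.abs_cdf(0.0) >= q:
            return 0.0
        hi = 10.0 + 40.0 * float(np.max(self.taus))
        return float(brentq(lambda x: float(self.abs_cdf(x)) - q, 0.0, hi,
                            xtol=1e-12))


@dataclass(frozen=True)
class PosteriorSNR:
    """Conditional mixture of SNR given an observed z.

    Component k: probability pi_k, mean mu_k = z tau_k^2/sigma_k^2,
    variance v_k = tau_k^2/sigma_k^2 (a shrinkage of z toward 0).
    """

    component_probs: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def mean(self) -> float:
        return float(self.component_probs @ self.means)


@dataclass
class FitReport:
    """Result of a weighted EM fit."""

    mixture: ZMixture
    loglik: float
    n_iter: int
    converged: bool
    restarts_used: int
    seed: int | None
    n_obs: int = 0
    n_studies: int | None = None


def z_density(mix: ZMixture, z) -> np.ndarray | float:
    """Marginal density f(z) = sum_k w_k phi(z/sigma_k)/sigma_k."""
    out = mix.pdf(z)
    return float(out) if np.isscalar(z) else out


def posterior_snr(mix: ZMixture, z: float) -> PosteriorSNR:
    """Closed-form conditional law of SNR given z under the fitted mixture."""
    z = float(z)
    s2 = mix.sigmas**2
    shrink = (s2 - 1.0) / s2
    log_pi = (np.log(np.maximum(mix.weights, 1e-300)) - np.log(mix.sigmas)
              - 0.5 * z**2 / s2)
    pi = np.exp(log_pi - logsumexp(log_pi))
    pi /= pi.sum()
    return PosteriorSNR(component_probs=pi, means=z * shrink, variances=shrink)


def deconvolve(mix: ZMixture) -> SNRMixture:
    """Subtract the unit estimation-noise variance: tau_k = sqrt(sigma_k^2 - 1)."""
    s2 = mix.sigmas**2
    if np.any(s2 < 1.0 - 1e-12):
        raise ValidationError("cannot deconvolve: sigma < 1")
    return SNRMixture(weights=mix.weights.copy(),
                      taus=np.sqrt(np.maximum(s2 - 1.0, 0.0)))


def reconvolve(snr_mix: SNRMixture) -> ZMixture:
    """Add back unit noise variance: sigma_k = sqrt(tau_k^2 + 1)."""
    return ZMixture(weights=snr_mix.weights.copy(),
                    sigmas=np.sqrt(snr_mix.taus**2 + 1.0))


def _weighted_loglik(z2: np.ndarray, w_obs: np.ndarray,
                     w: np.ndarray, s: np.ndarray) -> float:
    lp = (np.log(np.maximum(w, 1e-300)) - np.log(s) - _LOG_SQRT_2PI
          - 0.5 * z2[:, None] / s**2)
    return float(w_obs @ logsumexp(lp, axis=1))


def _em_once(z2: np.ndarray, w_obs: np.ndarray, w0: np.ndarray, s0: np.ndarray,
             tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    w, s = w0.copy(), s0.copy()
    total_w = w_obs.sum()
    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        lp = (np.log(np.maximum(w, 1e-300)) - np.log(s) - _LOG_SQRT_2PI
              - 0.5 * z2[:, None] / s**2)
        lse = logsumexp(lp, axis=1)
        ll = float(w_obs @ lse)
        r = np.exp(lp - lse[:, None]) * w_obs[:, None]   # weighted responsibilities
        rk = r.sum(axis=0)
        w = rk / total_w
        # constrained M-step: sigma^2 floored at the unit noise variance
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = np.where(rk > 0, (z2 @ r) / np.maximum(rk, 1e-300), 1.0)
        s = np.sqrt(np.maximum(s2, 1.0))
        if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and it > 1:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return w, s, ll_prev, it, converged


def _finalize(w: np.ndarray, s: np.ndarray,
              prune_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Sort by sigma, merge numerically duplicate components, prune empty ones."""
    order = np.argsort(s)
    w, s = w[order], s[order]
    keep_w, keep_s = [], []
    for wi, si in zip(w, s):
        if keep_s and abs(si - keep_s[-1]) <= 1e-6 * max(1.0, keep_s[-1]):
            keep_w[-1] += wi
        else:
            keep_w.append(wi)
            keep_s.append(si)
    w = np.asarray(keep_w)
    s = np.asarray(keep_s)
    mask = w > prune_tol
    if not mask.any():
        mask = w == w.max()
    w, s = w[mask], s[mask]
    return w / w.sum(), s


def _init_sigmas(K: int) -> np.ndarray:
    if K == 1:
        return np.array([2.0])
    return np.geomspace(1.1, 8.0, K)


def fit_z_mixture(z, weights=None, K: int = 4, *, tol: float = 1e-9,
                  max_iter: int = 10_000, n_restarts: int = 5,
                  seed: int | None = 0) -> FitReport:
    """Weighted maximum-likelihood fit of the zero-mean scale mixture of z.

    Maximizes sum_ij w_ij log f(z_ij) by EM with the sigma >= 1 floor applied
    in the M-step (the floor keeps the deconvolution well defined).  The best
    of ``n_restarts`` jittered initializations is returned; the first restart
    starts from the unjittered geometric ladder (1.1 ... 8).  Deterministic
    given ``seed``.
    """
    if K < 1:
        raise ConfigError("K must be >= 1")
    z = np.asarray(z, dtype=float).ravel()
    if weights is None:
        weights = np.ones_like(z)
    w_obs = np.asarray(weights, dtype=float).ravel()
    if z.shape != w_obs.shape:
        raise ValidationError("z and weights must have matching length")
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(w_obs)):
        raise ValidationError("non-finite z or weights")
    if np.any(w_obs <= 0):
        raise ValidationError("weights must be strictly positive")
    if np.unique(z).size < K:
        raise ValidationError(f"need at least K={K} distinct z values")

    rng = np.random.default_rng(seed)
    z2 = z**2
    base = _init_sigmas(K)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            s0 = base.copy()
        else:
            s0 = np.maximum(base * np.exp(rng.normal(0.0, 0.3, size=K)), 1.0)
            s0.sort()
        w0 = np.full(K, 1.0 / K)
        w_fit, s_fit, ll, n_iter, conv = _em_once(z2, w_obs, w0, s0, tol, max_iter)
        if best is None or ll > best[2]:
            best = (w_fit, s_fit, ll, n_iter, conv)
    w_fit, s_fit, ll, n_iter, conv = best
    w_fin, s_fin = _finalize(w_fit, s_fit)
    mix = ZMixture(weights=w_fin, sigmas=s_fin)
    # loglik reported for the finalized (merged/pruned) mixture
    ll_fin = _weighted_loglik(z2, w_obs, w_fin, s_fin)
    return FitReport(mixture=mix, loglik=ll_fin, n_iter=n_iter, converged=conv,
                     restarts_used=max(1, n_restarts), seed=seed, n_obs=z.size)


def fit_table(table, K: int = 4, **options) -> FitReport:
    """Fit the z mixture to an :class:`~replimix.ingest.EffectTable`."""
    report = fit_z_mixture(table.z, table.weights, K=K, **options)
    report.n_studies = table.n_studies
    return report


MODEL_FORMAT_VERSION = 1


def save_model(report: FitReport, path: str | Path) -> None:
    """Serialize a fitted mixture (JSON; floats round-trip exactly)."""
    payload = {
        "version": MODEL_FORMAT_VERSION,
        "K": report.mixture.K,
        "weights": report.mixture.weights.tolist(),
        "sigmas": report.mixture.sigmas.tolist(),
        "loglik": report.loglik,
        "n_obs": report.n_obs,
        "n_studies": report.n_studies,
        "seed": report.seed,
        "converged": report.converged,
        "n_iter": report.n_iter,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> FitReport:
    d = json.loads(Path(path).read_text())
    mix = ZMixture(np.asarray(d["weights"]), np.asarray(d["sigmas"]))
    return FitReport(mixture=mix, loglik=d["loglik"], n_iter=d.get("n_iter", 0),
                     converged=d.get("converged", True), restarts_used=0,
                     seed=d.get("seed"), n_obs=d.get("n_obs", 0),
                     n_studies=d.get("n_studies"))
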