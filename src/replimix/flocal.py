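"""Simultaneous confidence bands for replication probabilities (F-localization).

Rather than trusting the K-component point estimate, the band works over the
dense class of zero-centred Gaussian scale mixtures on a 365-point geometric
sigma grid (SNR scale, 1e-5 to ~516.3, ratio 1.05).  A Dvoretzky-Kiefer-
Wolfowitz (DKW) localization constrains the mixture's censored folded-normal
CDF of |z| to lie within eps of the study-weighted empirical CDF; |z| is
censored below 2.3 and above 10 for robustness near the significance cutoff
and at outliers.  Because effects within a study may be arbitrarily
correlated, the empirical CDF weights each study's effects by 1/n_j (each
study counts once) and eps uses J = number of independent studies.

For each z0 the replication probability of a grid mixture pi is the linear-
fractional functional N(pi)/D(pi) (numerator: density-weighted per-component
replication probabilities; denominator: the marginal density of z0).  Its
extrema over the localization set are found by a Charnes-Cooper transform
to a pair of linear programs; the shared feasible set makes the band
simultaneous over all z0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.stats import norm

from .errors import EmptyResultError, InfeasibleBandError
from .ingest import EffectTable
from .replication import significance_threshold

__all__ = [
    "SigmaGrid",
    "CensorSpec",
    "DKWLocalization",
    "FLocalBand",
    "build_sigma_grid",
    "weighted_folded_ecdf",
    "dkw_epsilon",
    "model_cdf_matrix",
    "band_for_replication",
    "replication_band",
]


@dataclass(frozen=True)
class SigmaGrid:
    """Geometric grid of SNR-scale standard deviations for the mixture class."""

    values: np.ndarray

    @property
    def G(self) -> int:
        return int(self.values.size)

    @property
    def z_scales(self) -> np.ndarray:
        """Implied z-scale standard deviations sqrt(1 + sigma^2)."""
        return np.sqrt(1.0 + self.values**2)


@dataclass(frozen=True)
class CensorSpec:
    """Censoring bounds for |z|: values below/above become interval cells."""

    lower: float = 2.3
    upper: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper:
            raise ValueError("require 0 < lower < upper")


@dataclass(frozen=True)
class DKWLocalization:
    """Study-weighted censored empirical CDF of |z| with its DKW half-width."""

    eval_points: np.ndarray
    emp_cdf: np.ndarray
    below_mass: float
    above_mass: float
    censor: CensorSpec
    J: int
    alpha_band: float = 0.05
    epsilon: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "epsilon",
                           dkw_epsilon(self.J, self.alpha_band))


@dataclass(frozen=True)
class FLocalBand:
    """Simultaneous lower/upper replication-probability bounds on a z grid."""

    z_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    m: float
    feasible: bool
    J: int
    epsilon: float
    censor: CensorSpec


def build_sigma_grid(n: int = 365, first: float = 1e-5,
                     ratio: float = 1.05) -> SigmaGrid:
    """The 365-component geometric sigma grid 1e-5 * 1.05^j, j = 0..364.

    The last element is ~516.3; one more ratio step would exceed that cap.
    """
    return SigmaGrid(values=first * ratio ** np.arange(n))


def dkw_epsilon(J: int, alpha_band: float = 0.05) -> float:
    """DKW half-width sqrt(ln(2/alpha) / (2 J)), J = number of studies."""
    if J < 1:
        raise ValueError("J must be >= 1")
    return float(np.sqrt(np.log(2.0 / alpha_band) / (2.0 * J)))


def default_eval_points(censor: CensorSpec = CensorSpec(),
                        n: int = 200) -> np.ndarray:
    return np.linspace(censor.lower, censor.upper, n)


def weighted_folded_ecdf(table: EffectTable, censor: CensorSpec = CensorSpec(),
                         eval_points=None, alpha_band: float = 0.05) -> DKWLocalization:
    """Study-weighted empirical CDF of |z|, censored outside [lower, upper].

    Each effect contributes weight w_ij / J (so each study counts once and
    the total mass is 1).  The CDF is evaluated only at points inside the
    censor window; the masses below ``lower`` and above ``upper`` are
    returned as two censored-cell totals.
    """
    if eval_points is None:
        eval_points = default_eval_points(censor)
    eval_points = np.asarray(eval_points, dtype=float)
    eval_points = eval_points[(eval_points >= censor.lower)
                              & (eval_points <= censor.upper)]
    z_abs = np.abs(table.z)
    w = table.weights
    J = table.n_studies
    total = w.sum()           # == J by construction
    wn = w / total
    inside = (z_abs >= censor.lower) & (z_abs <= censor.upper)
    if not inside.any():
        raise EmptyResultError("no observations inside the censor window")
    below = float(wn[z_abs < censor.lower].sum())
    above = float(wn[z_abs > censor.upper].sum())
    order = np.argsort(z_abs)
    z_sorted = z_abs[order]
    cum = np.cumsum(wn[order])
    idx = np.searchsorted(z_sorted, eval_points, side="right")
    emp = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    return DKWLocalization(eval_points=eval_points, emp_cdf=emp,
                           below_mass=below, above_mass=above,
                           censor=censor, J=J, alpha_band=alpha_band)


def model_cdf_matrix(grid: SigmaGrid, censor: CensorSpec = CensorSpec(),
                     eval_points=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Model CDF of |z| per grid component: folded normal with scale sqrt(1+sigma^2).

    Returns ``(A, below, above)``: ``A[t, j] = P(|z| <= t | component j)``
    for each eval point t, plus the two censored-cell rows
    ``below[j] = P(|z| < lower)`` and ``above[j] = P(|z| > upper)``.
    """
    if eval_points is None:
        eval_points = default_eval_points(censor)
    eval_points = np.asarray(eval_points, dtype=float)
    s = grid.z_scales
    A = 2.0 * norm.cdf(eval_points[:, None] / s) - 1.0
    below = 2.0 * norm.cdf(censor.lower / s) - 1.0
    above = 2.0 * norm.sf(censor.upper / s)
    return A, below, above


def _component_rep_probs(grid: SigmaGrid, z0: float, m: float,
                         c: float) -> np.ndarray:
    """Replication probability of |z0| under each single grid component.

    Component j: SNR-scale sigma_j plays the role of tau, so given z0 the
    posterior is N(z0 sigma_j^2/(1+sigma_j^2), sigma_j^2/(1+sigma_j^2)).
    At z0 = 0 the direction-free (two-tail) probability is used.
    """
    t2 = grid.values**2
    shrink = t2 / (1.0 + t2)
    sd = np.sqrt(m * shrink + 1.0)
    z0 = abs(float(z0))
    mu = z0 * shrink
    p = norm.sf((c - np.sqrt(m) * mu) / sd)
    if z0 == 0.0:
        p = 2.0 * norm.sf(c / sd)
    return p


def band_for_replication(localization: DKWLocalization, grid: SigmaGrid,
                         z_grid, m: float = 1.0, alpha: float = 0.05,
                         A_cached=None) -> FLocalBand:
    """Extremize the replication probability over the DKW feasible set.

    For each z0, solves the pair of linear programs obtained from the
    linear-fractional objective N(pi)/D(pi) by the Charnes-Cooper transform
    (variables y = t*pi, t > 0, with D(y) = 1).  All z0 share one feasible
    set, so the band is simultaneous at level 1 - alpha_band.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    eps = localization.epsilon
    if A_cached is None:
        A, below, above = model_cdf_matrix(grid, localization.censor,
                                           localization.eval_points)
    else:
        A, below, above = A_cached
    G = grid.G
    c_sig = significance_threshold(alpha)

    # constraint rows: interior eval points + the two censored cells
    rows = np.vstack([A, below[None, :], above[None, :]])
    b = np.concatenate([localization.emp_cdf,
                        [localization.below_mass, localization.above_mass]])
    # |rows @ pi - b| <= eps, homogenized:  rows@y - (b+eps) t <= 0
    #                                      -rows@y + (b-eps) t <= 0
    A_ub = np.vstack([
        np.hstack([rows, -(b + eps)[:, None]]),
        np.hstack([-rows, (b - eps)[:, None]]),
    ])
    b_ub = np.zeros(A_ub.shape[0])
    ones_row = np.concatenate([np.ones(G), [-1.0]])   # sum y - t = 0

    s2 = grid.z_scales
    lower_out = np.empty(z_grid.size)
    upper_out = np.empty(z_grid.size)
    feasible = True
    for i, z0 in enumerate(z_grid):
        f_j = norm.pdf(abs(z0) / s2) / s2             # marginal density at z0
        r_j = _component_rep_probs(grid, z0, m, c_sig)
        A_eq = np.vstack([np.concatenate([f_j, [0.0]]), ones_row])
        b_eq = np.array([1.0, 0.0])
        obj = np.concatenate([f_j * r_j, [0.0]])
        res_lo = linprog(obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                         bounds=(0, None), method="highs")
        res_hi = linprog(-obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                         bounds=(0, None), method="highs")
        if not (res_lo.success and res_hi.success):
            raise InfeasibleBandError(
                "F-localization infeasible or unbounded at z0="
                f"{z0:g} (status {res_lo.status}/{res_hi.status}); consider a "
                "wider censor window or a larger alpha_band")
        lower_out[i] = res_lo.fun
        upper_out[i] = -res_hi.fun
    lower_out = np.clip(lower_out, 0.0, 1.0)
    upper_out = np.clip(upper_out, 0.0, 1.0)
    return FLocalBand(z_grid=z_grid, lower=lower_out, upper=upper_out, m=m,
                      feasible=feasible, J=localization.J, epsilon=eps,
                      censor=localization.censor)


def replication_band(table: EffectTable, z_grid, m: float = 1.0,
                     alpha: float = 0.05, alpha_band: float = 0.05,
                     censor: CensorSpec = CensorSpec(), n_eval: int = 200,
                     grid: SigmaGrid | None = None) -> FLocalBand:
    """End-to-end simultaneous band from a weighted effect table."""
    if grid is None:
        grid = build_sigma_grid()
    pts = default_eval_points(censor, n_eval)
    loc = weighted_folded_ecdf(table, censor, pts, alpha_band)
    return band_for_replication(loc, grid, z_grid, m=m, alpha=alpha)
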