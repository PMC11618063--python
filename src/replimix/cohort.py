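"""Synthetic meta-analytic cohorts with known signal-to-noise ground truth.

Every downstream stage (mixture fit, deconvolution, replication curves,
F-localization bands) is testable against this generator because the true
SNR of each effect is recorded in a sidecar table.

Generative model, per study j:

* the number of effects n_j is drawn from a zero-truncated Poisson (or fixed);
* a mixture component k_j is drawn from the true SNR mixture's weights;
* a study latent u_j ~ N(0, rho * tau_{k_j}^2) is shared by all of the
  study's effects, producing exchangeable within-study correlation rho of
  the SNR;
* each effect i gets SNR_ij = u_j + e_ij with e_ij ~ N(0, (1-rho) tau_{k_j}^2),
  so marginally SNR_ij follows the true mixture exactly;
* z_ij = SNR_ij + standard normal estimation noise, SE_ij is log-normal,
  es = z * se and var = se^2.

An optional significance-based thinning operator drops non-significant
effects with probability 1 - s, emulating selective reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import EffectTable, compute_weights
from .mixture import SNRMixture
from .replication import significance_threshold

__all__ = ["CohortConfig", "generate_cohort", "apply_selection"]

_EFFECT_TYPES = ("SMD", "lnRR", "Zr", "other")

#: default effect-type composition of the emulated database
_DEFAULT_TYPE_PROBS = (0.45, 0.36, 0.15, 0.04)

#: studies per synthetic meta-analysis (cosmetic grouping of study ids)
_STUDIES_PER_META = 28


def _default_truth() -> SNRMixture:
    # two-component truth with z-scale sigmas (1.5, 4.0): a mildly and a
    # strongly informative component
    return SNRMixture(weights=np.array([0.6, 0.4]),
                      taus=np.sqrt(np.array([1.5, 4.0]) ** 2 - 1.0))


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``effects_per_study`` is either a positive int (fixed n_j) or a pair
    ``("ztpoisson", lam)`` for a zero-truncated Poisson with rate ``lam``
    (truncated mean lam / (1 - exp(-lam)); the default rate 6.79 gives a
    mean of ~6.8 effects per study).  ``within_study_share`` (rho) is the
    fraction of SNR variance shared within a study.  ``selection_prob`` (s)
    is the retention probability of non-significant effects; 1 disables
    selection.
    """

    n_studies: int = 1000
    effects_per_study: int | tuple[str, float] = ("ztpoisson", 6.79)
    true_mixture: SNRMixture = field(default_factory=_default_truth)
    within_study_share: float = 0.5
    se_law: tuple[float, float] = (-0.5, 0.6)
    effect_type_probs: tuple[float, float, float, float] = _DEFAULT_TYPE_PROBS
    selection_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        if not 0.0 <= self.within_study_share <= 1.0:
            raise ConfigError("within_study_share must be in [0, 1]")
        if not 0.0 < self.selection_prob <= 1.0:
            raise ConfigError("selection_prob must be in (0, 1]")
        p = np.asarray(self.effect_type_probs, dtype=float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("effect_type_probs must be a length-4 simplex")
        if isinstance(self.effects_per_study, int):
            if self.effects_per_study < 1:
                raise ConfigError("fixed effects_per_study must be >= 1")
        else:
            kind, lam = self.effects_per_study
            if kind != "ztpoisson":
                raise ConfigError(f"unknown effects_per_study law {kind!r}")
            if lam <= 0:
                raise ConfigError("ztpoisson rate must be > 0")


def _rng(seed: int) -> np.random.Generator:
    # counter-based bit generator: reproducible, cheaply seedable
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))


def _draw_n_effects(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.effects_per_study, int):
        return np.full(cfg.n_studies, cfg.effects_per_study, dtype=np.int64)
    _, lam = cfg.effects_per_study
    n = rng.poisson(lam, size=cfg.n_studies)
    while np.any(n == 0):   # zero-truncation by redraw
        zeros = n == 0
        n[zeros] = rng.poisson(lam, size=int(zeros.sum()))
    return n.astype(np.int64)


def generate_cohort(config: CohortConfig) -> tuple[EffectTable, pd.DataFrame]:
    """Generate a cohort and its ground-truth sidecar.

    Returns ``(table, truth)`` where ``truth`` has one row per effect with
    columns ``effect_id, study_id, component, study_latent, snr``.
    Deterministic given ``config.seed`` (draws happen in a fixed order).
    """
    cfg = config
    rng = _rng(cfg.seed)
    truth_mix = cfg.true_mixture
    rho = cfg.within_study_share

    n_j = _draw_n_effects(cfg, rng)
    J = cfg.n_studies
    N = int(n_j.sum())

    comp = rng.choice(truth_mix.K, size=J, p=truth_mix.weights / truth_mix.weights.sum())
    tau_j = truth_mix.taus[comp]
    u_j = rng.normal(0.0, 1.0, size=J) * np.sqrt(rho) * tau_j

    study_of = np.repeat(np.arange(J), n_j)
    e = rng.normal(0.0, 1.0, size=N) * np.sqrt(1.0 - rho) * tau_j[study_of]
    snr = u_j[study_of] + e
    z = snr + rng.normal(0.0, 1.0, size=N)
    loc, scale = cfg.se_law
    se = rng.lognormal(loc, scale, size=N)
    etype = rng.choice(len(_EFFECT_TYPES), size=N,
                       p=np.asarray(cfg.effect_type_probs, dtype=float))

    study_ids = np.array([f"S{j:06d}" for j in range(J)])
    meta_ids = np.array([f"M{j // _STUDIES_PER_META:05d}" for j in range(J)])
    data = pd.DataFrame({
        "meta_id": meta_ids[study_of],
        "study_id": study_ids[study_of],
        "effect_id": [f"E{i}" for i in range(N)],
        "effect_type": np.asarray(_EFFECT_TYPES)[etype],
        "label": study_ids[study_of],
        "es": z * se,
        "se": se,
        "var": se**2,
        "z": z,
        "weight": np.nan,
    })
    table = compute_weights(EffectTable(data))
    truth = pd.DataFrame({
        "effect_id": data["effect_id"],
        "study_id": data["study_id"],
        "component": comp[study_of],
        "study_latent": u_j[study_of],
        "snr": snr,
    })
    if cfg.selection_prob < 1.0:
        table = apply_selection(table, cfg.selection_prob, seed=cfg.seed + 1)
        truth = truth[truth["effect_id"].isin(table.data["effect_id"])]
        truth = truth.reset_index(drop=True)
    return table, truth


def apply_selection(table: EffectTable, s: float, seed: int,
                    alpha: float = 0.05) -> EffectTable:
    """Thin non-significant effects: keep |z| > c always, others w.p. ``s``.

    A minimal model of selective reporting; ``s = 1`` is the identity.
    Weights are recomputed on the retained records.
    """
    if not 0.0 < s <= 1.0:
        raise ConfigError("retention probability s must be in (0, 1]")
    if s == 1.0:
        return table
    rng = _rng(seed)
    c = significance_threshold(alpha)
    z = table.z
    keep = (np.abs(z) > c) | (rng.uniform(size=z.size) < s)
    out = table.data.loc[keep].reset_index(drop=True)
    return compute_weights(EffectTable(out))
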