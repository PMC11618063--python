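# Methods

## Sampling model and deconvolution

Each observed effect i in study j contributes an estimate ES̄ with standard
error SE treated as known, so that ES̄ | ES ~ N(ES, SE²). Writing
z = ES̄/SE and SNR = ES/SE gives the unit-noise convolution

    z | SNR ~ N(SNR, 1).

The marginal of z is modelled as a zero-mean Gaussian *scale* mixture,

    f(z) = Σₖ wₖ φ(z/σₖ)/σₖ,  wₖ ≥ 0, Σ wₖ = 1, σₖ ≥ 1,

which forces the SNR distribution to be symmetric about zero — appropriate
when effect signs are essentially arbitrary coding choices across a large
heterogeneous database. The σₖ ≥ 1 floor makes the deconvolution
well defined: subtracting the unit noise variance yields the SNR mixture
with the same weights and τₖ = √(σₖ² − 1). A component at the boundary
σₖ = 1 is a point mass of true nulls (the parameter space is taken as the
closure; a strict inequality would admit no attainable maximizer).

The conditional law of SNR given z is available in closed form: component
k has posterior probability πₖ(z) ∝ wₖ φ(z/σₖ)/σₖ, and within component k,
SNR | z ~ N(z·τₖ²/σₖ², τₖ²/σₖ²) — a shrinkage of z toward zero, since
τₖ²/σₖ² < 1.

## Weighted maximum likelihood

Studies contribute unequal numbers of correlated effects, so each effect is
weighted by 1/nⱼ (nⱼ = effects in its study) and the weighted log-likelihood
Σ wᵢⱼ log f(zᵢⱼ) is maximized by EM. The per-study total weight is
normalized to 1, so the summed weight equals the number of independent
studies J and the weighted likelihood scales like a J-study sample — the
same J that drives the DKW band width below.

Numerical choices:

- K = 4 components by default (configurable; sensitivity to K is worth
  checking on any new database).
- Initialization: σ on the geometric ladder 1.1 … 8, jittered
  multiplicatively (log-normal, sd 0.3) on restarts 2…R; uniform weights.
  Default R = 5 restarts; mixture likelihoods are multimodal.
- M-step floor: the unconstrained σₖ² update (a weighted mean of z²) is
  clipped at 1; since the component likelihood is unimodal in σ², the
  clipped update is the constrained maximizer and EM monotonicity is
  preserved.
- Convergence: relative change of the weighted log-likelihood < 1e-9 or
  10,000 iterations.
- Finalization: components are sorted by σ, numerically duplicate σ values
  (within 1e-6 relative) are merged, and components with weight < 1e-8 are
  pruned; the effective K is reported.

## Replication probability, power, and planning

A successful exact replication at two-sided level α means
z·z_repl > 0 and |z_repl| > c with c = Φ⁻¹(1 − α/2) (1.959964… at
α = 0.05; the exact quantile is used rather than the printed 1.96 so that
identities like power(0) = α hold exactly). If the replication sample is
m-fold larger, its SNR is √m times the original's, hence
z_repl | SNR ~ N(√m·SNR, 1) and, for z > 0,

    P(success | z) = Σₖ πₖ(z) · [1 − Φ((c − √m·μₖ(z)) / √(m·vₖ + 1))],

with μₖ, vₖ the posterior component means/variances; the z < 0 case follows
by symmetry. At z = 0 the direction requirement is ill-posed; the
significance-only (two-tail) probability is returned with a warning so that
curves can still be evaluated at the grid origin. As m → 0 the probability
tends to α/2 (pure noise, correct sign by chance); it is increasing in m
whenever the posterior puts mass on nonzero SNR.

Power is the unconditional functional Φ(−c − SNR) + 1 − Φ(c − SNR),
deliberately including wrong-direction rejections. It is strictly
increasing in |SNR|, so the power distribution is the push-forward of the
|SNR| distribution: P(power ≤ p) = P(|SNR| ≤ snr(p)), with snr(p) obtained
by bisection on |SNR| ∈ [0, 50] (tolerance 1e-10), and power quantiles are
the power at the |SNR| quantiles. Requested power levels must lie in
(α, 1): power cannot fall below the test's size.

`required_sample_factor` finds the smallest m ∈ [1e-6, 1e4] with
replication probability ≥ target by bisection on log m (probability
tolerance 1e-4); it returns a continuous m (the CLI also prints the
ceiling). If even m = 1e4 falls short — e.g. under a pure-null posterior,
whose supremum is α/2 — an error reports the estimated supremum.

Average replicability is the weight-renormalized mean of the per-effect
replication probabilities over the effects meeting a condition (default:
|z| > c, "statistically significant originals"), using the 1/nⱼ cluster
weights; an unweighted switch is available in the API via `weights=None`.

## F-localization confidence bands

The band does not trust the 4-component point estimate. Instead it works
over the dense class of zero-centred Gaussian scale mixtures on the fixed
geometric grid σ ∈ {1e-5, 1e-5·1.05, …}, 365 components, last value
≈ 516.3 (one more 1.05 step would exceed that cap). Component j induces
|z| ~ folded N(0, 1 + σⱼ²).

The data enter through the study-weighted empirical CDF of |z|: each effect
carries weight wᵢⱼ/J, so each study contributes a weight-1 sub-ECDF and the
independent unit is the study. |z| is censored below 2.3 and above 10 —
values in the censored regions are used only through their two cell masses
— for robustness to mild p-hacking near the significance cutoff and to
outliers. The localization constrains a candidate weight vector π by
|A·π − F̂| ≤ ε at 200 equally spaced evaluation points in [2.3, 10] and at
the two censored cells, with the DKW half-width

    ε = √(ln(2/α_band) / (2J)),  J = number of independent studies.

Using study-level J (not the effect count) is this package's handling of
arbitrary within-study correlation; it is documented as an approximation —
it may be conservative or anti-conservative relative to more refined
dependent-data constructions, and the coverage simulation in the test suite
(200 cohorts at J = 2,000 under the generator's default dependence) is the
empirical check.

For a query z₀ the replication probability of a grid mixture π is the
linear-fractional functional N(π)/D(π), where D(π) = Σⱼ πⱼ fⱼ(z₀) is the
marginal density at z₀ (component scale √(1+σⱼ²)) and N(π) weights each
component's closed-form replication probability by its density. Its
minimum and maximum over the feasible set are obtained via the
Charnes–Cooper transform (y = tπ, D(y) = 1), giving one linear-program pair
per z₀, solved with HiGHS through `scipy.optimize.linprog`. Every z₀
shares the same feasible set, so the band is simultaneous at level
1 − α_band; band values are clipped to [0, 1]. An empty feasible set
raises an error suggesting a wider censor window or larger α_band.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
ground truth recorded per effect:

- J studies; effects per study from a zero-truncated Poisson with rate
  λ = 6.79 by default (truncated mean ≈ 6.8, matching the emulated
  database's 88,218 effects / 12,927 studies), or a fixed count.
- A mixture component is drawn *per study*; a share ρ (default 0.5) of the
  component's SNR variance is a study-level latent shared by all of the
  study's effects, the rest is effect-level — the simplest mechanism giving
  exchangeable within-study SNR correlation ρ. The marginal SNR law is the
  true mixture exactly, for any ρ.
- z = SNR + N(0, 1); SE ~ log-normal(−0.5, 0.6) (positive and right-skewed;
  the specific values are stand-ins, since no empirical SE law is imposed),
  ES̄ = z·SE.
- Effect-type labels SMD/lnRR/Zr/other are drawn with probabilities
  0.45/0.36/0.15/0.04 — the composition of the emulated database — and are
  purely cosmetic.
- Default true SNR mixture: weights (0.6, 0.4) with z-scale sigmas
  (1.5, 4.0), i.e. a mildly and a strongly informative component; a
  realistic two-group world with many low-power and some high-power
  studies. It is a modelling default, not an estimate of any particular
  database.
- Optional selection thinning: significant effects (|z| > c) are always
  retained, others with probability s. This emulates selective reporting;
  fits on thinned cohorts overstate replicability, which the tests verify
  directionally.

All randomness flows from one seed through a counter-based Philox stream
with draws in a fixed order, so cohorts are byte-identical given the seed.

What the generator does *not* emulate: empirical SE or cluster-size
distributions of any real database, between-study heterogeneity in
replications (replications are idealized and exact), or realistic
p-hacking beyond the thinning operator. Passing recovery and coverage
tests therefore demonstrates correctness of the estimator under its own
assumptions, not robustness to their violation on real data.

## Problem sizes used in the checks

Parameter recovery is run at J = 20,000 independent studies (one effect
each, ρ = 0) against the (0.6, 0.4)/(1.5, 4.0) truth; Monte-Carlo
equivalence of the closed form uses 10⁶ draws per triple; band coverage
uses 200 cohorts at J = 2,000 with default dependence, evaluated on a
5-point z grid (simultaneity over the shared feasible set applies to any
sub-grid). The acceptance script emulates the full database scale
(J = 12,927).

## Known limitations

- Symmetric, zero-mean SNR mixtures only; no asymmetric or shifted
  components.
- All replicability estimates assume no selective reporting; under
  publication bias they are upper bounds, and the censoring in the band
  construction does not confer robustness to selection.
- The point estimate's K is fixed a priori; only the band construction is
  free of a fixed K.
- The study-level DKW extension is an approximation for dependent data
  (see above).
- Duplicate-study detection is an exact match on a normalized label key;
  fuzzier manual curation of real databases may differ slightly.
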