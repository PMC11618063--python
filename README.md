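# replimix

**Replication-probability estimation for meta-analytic effect sizes** via
empirical-Bayes deconvolution of z statistics and simultaneous
F-localization confidence bands.

## The problem

Large collections of published effect sizes (ecology and evolution
meta-analyses being the motivating case) let us ask, *in silico*: if a study
that reported z = ES̄/SE were repeated exactly, what is the probability the
replication would again be statistically significant in the same direction?
The true effect ES is never observed, but because

- ES̄ | ES ~ N(ES, SE²), so z | SNR ~ N(SNR, 1) with SNR = ES/SE,

the marginal distribution of the observed z statistics is the distribution
of the signal-to-noise ratio (SNR) convolved with standard normal noise.
`replimix` fits a zero-mean Gaussian scale mixture

f(z) = Σₖ wₖ φ(z/σₖ)/σₖ,  σₖ ≥ 1,

to the z statistics by weighted maximum likelihood (each effect weighted by
1/nⱼ so every study counts once), and *deconvolves* it by subtracting the
unit noise variance: g(SNR) = Σₖ wₖ φ(SNR/τₖ)/τₖ with τₖ = √(σₖ² − 1).
From the resulting joint law of (z, SNR) it computes, in closed form:

- the conditional probability that an exact replication with an m-fold
  larger sample (SNR scales with √m) satisfies
  z·z_repl > 0 and |z_repl| > Φ⁻¹(1 − α/2);
- the distribution of statistical power Φ(−c − SNR) + 1 − Φ(c − SNR);
- the fold-increase m needed to reach a target replication probability;
- simultaneous 95% confidence bands for the whole replication curve, by
  localizing the mixing distribution over a dense 365-component scale grid
  with a study-level Dvoretzky–Kiefer–Wolfowitz constraint on the censored
  folded-|z| CDF and extremizing the replication functional by linear
  programming (Charnes–Cooper transform).

A synthetic-cohort generator with known ground truth (clustered effects,
within-study SNR correlation, optional significance-based selection
thinning) makes every stage testable without any external data. Estimates
assume no selective reporting; under publication bias they are upper
bounds.

## Worked example

```python
import numpy as np
import replimix as rm

cfg = rm.CohortConfig(n_studies=5000, seed=7)        # known ground truth
table, truth = rm.generate_cohort(cfg)
report = rm.fit_table(table, K=4, n_restarts=5, seed=1)
mix = report.mixture
for z in (1.96, 3.29):
    print(f"P(successful replication | z={z}) = "
          f"{rm.replication_probability(mix, z):.3f}")
m = rm.required_sample_factor(mix, 1.96, 0.75)
print(f"fold-increase to reach 75% from z=1.96: {m:.2f}")
band = rm.replication_band(table, [1.96])
print(f"95% simultaneous band at z=1.96: "
      f"[{band.lower[0]:.3f}, {band.upper[0]:.3f}]")
```

prints

```
P(successful replication | z=1.96) = 0.318
P(successful replication | z=3.29) = 0.680
fold-increase to reach 75% from z=1.96: 8.26
95% simultaneous band at z=1.96: [0.260, 0.373]
```

A study that was just significant (z = 1.96) has about a 32% chance of a
successful exact replication under this cohort's effect-size distribution,
while a strongly significant one (z = 3.29) has about 68%; reaching 75%
replicability from the marginal study requires roughly an eight-fold larger
sample. The band is simultaneous: with 95% confidence it covers the
replication probability at *every* z at once.

The same pipeline runs on real data from the shell:

```bash
replimix fit --input effects.csv --es-col es --var-col var \
    --study-col study_id --meta-col meta_id --out model.json
replimix curve --model model.json --m 1 --out curve.csv
replimix plan --model model.json --z 1.96 --target 0.75
replimix band --input effects.csv --es-col es --var-col var \
    --study-col study_id --meta-col meta_id --out band.csv
```

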