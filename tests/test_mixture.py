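import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import kstest, norm

import replimix as rm
from replimix.errors import ConfigError, ValidationError
from replimix.mixture import _em_once, _weighted_loglik


def test_z_density_values(two_comp_mixture, null_mixture):
    assert rm.z_density(null_mixture, 0.0) == pytest.approx(0.3989422804, abs=1e-8)
    assert rm.z_density(two_comp_mixture, 0.0) == pytest.approx(0.2992067103, abs=1e-8)
    # symmetric and strictly positive
    zs = np.linspace(-8, 8, 41)
    f = rm.z_density(two_comp_mixture, zs)
    assert np.allclose(f, f[::-1])
    assert np.all(f > 0)


def test_z_density_integrates_to_one(two_comp_mixture):
    total, _ = quad(lambda z: rm.z_density(two_comp_mixture, z), -50, 50,
                    limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_posterior_component_probs(two_comp_mixture):
    post = rm.posterior_snr(two_comp_mixture, 0.0)
    assert post.component_probs == pytest.approx([2 / 3, 1 / 3], abs=1e-12)
    assert np.all(post.means == 0.0)


def test_posterior_shrinkage_single_component():
    mix = rm.ZMixture(np.array([1.0]), np.array([np.sqrt(2.0)]))
    post = rm.posterior_snr(mix, 2.0)
    assert post.means[0] == pytest.approx(1.0)
    assert post.variances[0] == pytest.approx(0.5)


@settings(deadline=None, max_examples=50)
@given(z=st.floats(-10, 10),
       s2=st.floats(1.0, 30.0),
       s3=st.floats(1.0, 30.0),
       w1=st.floats(0.05, 0.9))
def test_posterior_mean_shrinks_toward_zero(z, s2, s3, w1):
    mix = rm.ZMixture(np.array([w1, 1 - w1]), np.array([s2, s3])) \
        if abs(s2 - s3) > 1e-6 else rm.ZMixture(np.array([1.0]), np.array([s2]))
    post = rm.posterior_snr(mix, z)
    assert abs(post.mean()) <= abs(z) + 1e-12
    assert post.component_probs.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all((post.variances >= 0) & (post.variances < 1))


def test_deconvolve_algebra():
    mix = rm.ZMixture(np.array([0.2, 0.3, 0.5]),
                      np.array([1.0, np.sqrt(2.0), np.sqrt(5.0)]))
    snr = rm.deconvolve(mix)
    assert snr.taus == pytest.approx([0.0, 1.0, 2.0])
    back = rm.reconvolve(snr)
    assert back.sigmas == pytest.approx(mix.sigmas)
    assert back.weights == pytest.approx(mix.weights)


def test_deconvolve_rejects_sigma_below_one():
    with pytest.raises(ValidationError):
        rm.ZMixture(np.array([1.0]), np.array([0.9]))


def test_em_loglik_monotone():
    rng = np.random.default_rng(0)
    z = rng.normal(0, 2.0, size=400)
    z2 = z**2
    w_obs = np.ones_like(z)
    lls = []
    for it in range(1, 12):
        w, s, _, _, _ = _em_once(z2, w_obs, np.array([0.5, 0.5]),
                                 np.array([1.1, 4.0]), tol=0.0, max_iter=it)
        lls.append(_weighted_loglik(z2, w_obs, w, s))
    assert np.all(np.diff(lls) >= -1e-9)


def test_fit_recovers_null():
    rng = np.random.default_rng(123)
    z = rng.normal(size=20_000)
    report = rm.fit_z_mixture(z, K=4, n_restarts=3, seed=0)
    mix = report.mixture
    stat = kstest(z, lambda x: mix.cdf(x)).statistic
    assert stat < 0.01
    snr = rm.deconvolve(mix)
    assert float(snr.weights @ snr.taus**2) < 0.05


def test_fit_deterministic_and_stable(truth_mixture):
    snr_mix = rm.deconvolve(truth_mixture)
    cfg = rm.CohortConfig(n_studies=5000, effects_per_study=1,
                          within_study_share=0.0, true_mixture=snr_mix, seed=4)
    table, _ = rm.generate_cohort(cfg)
    r1 = rm.fit_table(table, K=4, n_restarts=2, seed=7)
    r2 = rm.fit_table(table, K=4, n_restarts=2, seed=7)
    assert np.array_equal(r1.mixture.sigmas, r2.mixture.sigmas)
    assert r1.loglik == r2.loglik
    # restart stability: per-study loglik agrees across seeds
    J = table.n_studies
    lls = [rm.fit_table(table, K=4, n_restarts=3, seed=s).loglik / J
           for s in (1, 2, 3)]
    assert max(lls) - min(lls) < 1e-4


def test_fit_validation_errors():
    with pytest.raises(ConfigError):
        rm.fit_z_mixture([1.0, 2.0, 3.0], K=0)
    with pytest.raises(ValidationError):
        rm.fit_z_mixture([1.0, np.nan, 2.0], K=1)
    with pytest.raises(ValidationError):
        rm.fit_z_mixture([1.0, 1.0, 1.0], K=2)   # too few distinct values


def test_joint_consistency_marginalizes_back(truth_mixture):
    """Integrating the posterior of SNR against f(z) must return g(SNR)."""
    zg = np.linspace(-30, 30, 4001)
    dz = zg[1] - zg[0]
    sg = np.linspace(-12, 12, 601)
    fz = truth_mixture.pdf(zg)
    s2 = truth_mixture.sigmas**2
    shrink = (s2 - 1.0) / s2
    pi = np.exp(np.log(np.maximum(truth_mixture.weights, 1e-300))
                - np.log(truth_mixture.sigmas)
                - 0.5 * zg[:, None] ** 2 / s2)
    pi /= pi.sum(axis=1, keepdims=True)
    dens = np.zeros((zg.size, sg.size))
    for k in range(truth_mixture.K):
        mu = zg * shrink[k]
        sd = np.sqrt(shrink[k])
        dens += pi[:, [k]] * norm.pdf((sg[None, :] - mu[:, None]) / sd) / sd
    g_rec = (fz[:, None] * dens).sum(axis=0) * dz
    g_true = rm.deconvolve(truth_mixture).pdf(sg)
    tv = 0.5 * np.trapezoid(np.abs(g_rec - g_true), sg)
    assert tv < 1e-3


def test_model_serialization_roundtrip(tmp_path, truth_mixture):
    report = rm.FitReport(mixture=truth_mixture, loglik=-1234.5678901234567,
                          n_iter=17, converged=True, restarts_used=5, seed=3,
                          n_obs=100, n_studies=50)
    path = tmp_path / "model.json"
    rm.save_model(report, path)
    loaded = rm.load_model(path)
    assert np.array_equal(loaded.mixture.weights, report.mixture.weights)
    assert np.array_equal(loaded.mixture.sigmas, report.mixture.sigmas)
    assert loaded.loglik == report.loglik
    assert loaded.n_studies == 50
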