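import numpy as np
import pytest
from scipy.stats import norm

import replimix as rm
from replimix.errors import ConfigError, EmptyResultError, UnattainableError


def test_null_model_gives_alpha_half(null_mixture):
    for z in (0.5, 1.96, -3.0, 7.0):
        for m in (0.1, 1.0, 25.0):
            assert rm.replication_probability(null_mixture, z, m=m) == \
                pytest.approx(0.025, abs=1e-12)


def test_single_component_closed_form():
    # posterior given z=2 is N(1, 0.5); z_repl ~ N(1, 1.5)
    mix = rm.ZMixture(np.array([1.0]), np.array([np.sqrt(2.0)]))
    c = rm.significance_threshold()
    expected = norm.sf((c - 1.0) / np.sqrt(1.5))
    assert rm.replication_probability(mix, 2.0) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.217, abs=5e-4)


def test_symmetry_in_z(truth_mixture):
    for z in (0.3, 1.96, 4.2):
        assert rm.replication_probability(truth_mixture, z) == \
            rm.replication_probability(truth_mixture, -z)


def test_monotone_in_m_and_small_m_limit(truth_mixture):
    ms = np.array([1e-6, 0.01, 0.1, 1.0, 4.0, 100.0])
    ps = [rm.replication_probability(truth_mixture, 2.5, m=m) for m in ms]
    assert np.all(np.diff(ps) > 0)
    assert ps[0] == pytest.approx(0.025, abs=1e-3)


def test_z_zero_warns_and_reports_significance_only(truth_mixture):
    with pytest.warns(UserWarning, match="direction undefined"):
        p = rm.replication_probability(truth_mixture, 0.0)
    assert 0.0 < p < 1.0


def test_curve_null_constant_and_shape(null_mixture, truth_mixture):
    # z = 0 is the direction-free edge case (twice alpha/2 for the null);
    # everywhere else the null curve is flat at alpha/2
    at_zero = rm.replication_curve(null_mixture, [0.0])
    assert at_zero.point[0] == pytest.approx(0.05, abs=1e-12)
    zg = np.linspace(0.03, 6, 200)
    flat = rm.replication_curve(null_mixture, zg)
    assert np.allclose(flat.point, 0.025)
    curve = rm.replication_curve(truth_mixture, zg)
    assert np.all((curve.point >= 0) & (curve.point <= 1))
    assert np.all(np.diff(curve.point) > -1e-12)   # non-decreasing in z
    curve4 = rm.replication_curve(truth_mixture, zg, m=4.0)
    assert np.all(curve4.point[zg > 0] > curve.point[zg > 0])


def test_power_anchors():
    assert rm.power_of_snr(0.0) == pytest.approx(0.05, abs=1e-12)
    c = rm.significance_threshold()
    assert rm.power_of_snr(c) == pytest.approx(0.5 + norm.cdf(-2 * c), abs=1e-12)
    assert rm.power_of_snr(2.80) == pytest.approx(0.800, abs=1e-3)


def test_power_distribution_point_mass_null():
    null_snr = rm.SNRMixture(weights=np.array([1.0]), taus=np.array([0.0]))
    dist = rm.power_distribution(null_snr, p_grid=[0.06, 0.5, 0.9])
    assert np.allclose(dist.cdf, 1.0)   # all mass at power = alpha


def test_power_distribution_single_tau():
    snr = rm.SNRMixture(weights=np.array([1.0]), taus=np.array([1.0]))
    dist = rm.power_distribution(snr, p_grid=[0.5])
    # inverting the power functional at p=0.5 gives |SNR| ~ c
    assert dist.cdf[0] == pytest.approx(2 * norm.cdf(1.959964) - 1, abs=1e-3)


def test_power_median_is_power_of_median_snr(truth_mixture):
    snr = rm.deconvolve(truth_mixture)
    dist = rm.power_distribution(snr, quantiles=(0.5,))
    med_snr = snr.abs_quantile(0.5)
    assert dist.quantiles[0.5] == pytest.approx(rm.power_of_snr(med_snr),
                                                abs=1e-6)


def test_power_distribution_domain_error(truth_mixture):
    snr = rm.deconvolve(truth_mixture)
    with pytest.raises(ConfigError):
        rm.power_distribution(snr, p_grid=[0.04])
    with pytest.raises(ConfigError):
        rm.invert_power(1.0)


def test_average_replicability(null_mixture, truth_mixture):
    z = np.array([0.2, 2.5, -3.1, 1.0, 4.0])
    assert rm.average_replicability(null_mixture, z) == pytest.approx(0.025)
    # weighted average over the significant subset only
    w = np.array([1.0, 2.0, 1.0, 5.0, 1.0])
    got = rm.average_replicability(truth_mixture, z, w)
    probs = [rm.replication_probability(truth_mixture, zi) for zi in (2.5, -3.1, 4.0)]
    expected = np.average(probs, weights=[2.0, 1.0, 1.0])
    assert got == pytest.approx(expected, abs=1e-12)
    with pytest.raises(EmptyResultError):
        rm.average_replicability(truth_mixture, [0.1, -0.5])


def test_required_sample_factor_closed_form():
    mix = rm.ZMixture(np.array([1.0]), np.array([np.sqrt(2.0)]))
    m = rm.required_sample_factor(mix, 2.0, 0.5)
    assert m == pytest.approx(rm.significance_threshold() ** 2, abs=1e-3)


def test_required_sample_factor_already_achieved(truth_mixture):
    p1 = rm.replication_probability(truth_mixture, 3.0)
    m = rm.required_sample_factor(truth_mixture, 3.0, p1 - 0.05)
    assert m <= 1.0


def test_required_sample_factor_unattainable(null_mixture):
    with pytest.raises(UnattainableError) as exc:
        rm.required_sample_factor(null_mixture, 2.0, 0.5)
    assert exc.value.supremum == pytest.approx(0.025, abs=1e-6)


def test_oracle_equivalence_single_case(truth_mixture):
    """Light Monte-Carlo cross-check of the closed form (deeper sweep in the
    acceptance suite)."""
    rng = np.random.default_rng(77)
    z0, m = 2.2, 2.0
    n = 200_000
    post = rm.posterior_snr(truth_mixture, z0)
    comp = rng.choice(post.component_probs.size, size=n, p=post.component_probs)
    snr = rng.normal(post.means[comp], np.sqrt(post.variances[comp]))
    z_repl = rng.normal(np.sqrt(m) * snr, 1.0)
    c = rm.significance_threshold()
    p_mc = np.mean((z_repl * z0 > 0) & (np.abs(z_repl) > c))
    p_cf = rm.replication_probability(truth_mixture, z0, m=m)
    assert abs(p_mc - p_cf) < 3 * np.sqrt(p_cf * (1 - p_cf) / n)
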