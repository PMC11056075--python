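import math

import numpy as np
import pytest
from scipy import stats

from metapool.data import Design, Metric
from metapool.nnhm import (
    BayesMetaAnalysis,
    EffectPrior,
    HeterogeneityPrior,
    MixtureOfNormals,
    PriorFamily,
    conditional_mu_posterior,
    fit_nnhm,
    likelihood_given_tau,
    prior_density,
    shortest_interval,
)

from conftest import make_dataset

HN = HeterogeneityPrior.half_normal(0.5)
HC = HeterogeneityPrior.half_cauchy(0.5)


# ---------------------------------------------------------------------------
# priors


@pytest.mark.parametrize(
    "prior, tau, expected",
    [
        # analytic densities evaluated by hand
        (HN, 0.0, 2.0 / (0.5 * math.sqrt(2 * math.pi))),
        (HN, 0.5, 2.0 / (0.5 * math.sqrt(2 * math.pi)) * math.exp(-0.5)),
        (HC, 0.0, 2.0 / (math.pi * 0.5)),
        (HC, 0.5, 2.0 / (math.pi * 0.5) / 2.0),
    ],
)
def test_prior_density_closed_forms(prior, tau, expected):
    assert prior_density(prior, tau) == pytest.approx(expected, rel=1e-12)


def test_prior_tail_probabilities_at_0p4():
    """Analytic tail masses below tau = 0.4 for scale-0.5 priors."""
    assert HC.cdf(0.4) == pytest.approx((2 / math.pi) * math.atan(0.8), rel=1e-12)
    assert HN.cdf(0.4) == pytest.approx(math.erf(0.4 / (0.5 * math.sqrt(2))), rel=1e-12)


def test_prior_density_rejects_negative_tau():
    with pytest.raises(ValueError):
        prior_density(HN, -0.1)


def test_prior_cdf_limits_and_normalization():
    for prior in (HN, HC):
        assert prior.cdf(0.0) == 0.0
        assert prior.cdf(np.inf) == 1.0
        grid = np.linspace(0, 200, 400001)
        assert np.trapezoid(prior.pdf(grid), grid) == pytest.approx(1.0, abs=5e-3)


@pytest.mark.parametrize("x", [1.0, 2.0, 5.0])
def test_half_cauchy_has_heavier_tail(x):
    assert HC.cdf(x) < HN.cdf(x)  # i.e. P(tau > x) is larger under half-Cauchy


# ---------------------------------------------------------------------------
# conditional posterior and tau-likelihood


def test_conditional_mu_posterior_conjugate_example():
    ds = make_dataset([0.0], [1.0])
    mean, sd = conditional_mu_posterior(ds, EffectPrior(0.0, 2.0), tau=0.0)
    assert mean == 0.0
    assert sd == pytest.approx((1 + 0.25) ** -0.5, abs=1e-12)


def test_conditional_mu_posterior_vague_prior_limit(toy3):
    mean, _ = conditional_mu_posterior(toy3, EffectPrior(0.0, 1e8), tau=0.0)
    w = 1.0 / toy3.se**2
    fe = np.sum(w * toy3.y) / np.sum(w)
    assert mean == pytest.approx(fe, abs=1e-8)


@pytest.mark.parametrize("tau", [0.0, 0.3, 1.7])
def test_conditional_mu_posterior_symmetry(tau):
    ds = make_dataset([0.0, 0.0, 0.0], [0.4, 0.2, 0.9])
    mean, _ = conditional_mu_posterior(ds, EffectPrior(0.0, 2.0), tau=tau)
    assert mean == 0.0


def test_likelihood_given_tau_single_study_closed_form():
    # one study y=0, se=1, tau=0, prior N(0,2): y ~ N(0, 1 + 4)
    ds = make_dataset([0.0], [1.0])
    got = likelihood_given_tau(ds, EffectPrior(0.0, 2.0), 0.0)
    assert got == pytest.approx(stats.norm.logpdf(0.0, 0.0, math.sqrt(5.0)), rel=1e-12)


@pytest.mark.parametrize("tau", [0.0, 0.17, 0.5, 2.3])
def test_likelihood_given_tau_matches_dense_mvn(toy3, tau):
    """Rank-one closed form vs an explicit dense multivariate normal."""
    prior = EffectPrior(0.3, 2.0)
    cov = np.diag(toy3.se**2 + tau**2) + prior.sd**2 * np.ones((3, 3))
    expected = stats.multivariate_normal.logpdf(toy3.y, mean=np.full(3, prior.mean), cov=cov)
    got = likelihood_given_tau(toy3, prior, tau)
    assert got == pytest.approx(expected, rel=1e-11)


def test_likelihood_given_tau_continuity(toy3):
    taus = np.linspace(0, 3, 3000)
    ll = likelihood_given_tau(toy3, EffectPrior(0.0, 2.0), taus)
    assert np.all(np.isfinite(ll))
    assert np.max(np.abs(np.diff(ll))) < 0.1  # no jumps on a fine grid


# ---------------------------------------------------------------------------
# full fit


def test_fit_degenerate_scale_recovers_conjugate_posterior(toy3):
    """As the tau-prior scale -> 0 the fit reduces to the tau = 0 conjugate
    normal posterior and the CrI to its equal-tailed interval."""
    prior = EffectPrior(0.0, 2.0)
    res = fit_nnhm(toy3, HeterogeneityPrior.half_normal(1e-8), prior)
    mean, sd = conditional_mu_posterior(toy3, prior, tau=0.0)
    z = stats.norm.ppf(0.975)
    assert res.mu_median == pytest.approx(mean, abs=1e-6)
    assert res.cri_low == pytest.approx(mean - z * sd, abs=1e-5)
    assert res.cri_high == pytest.approx(mean + z * sd, abs=1e-5)
    # and the marginal likelihood reduces to the tau = 0 value
    assert res.log_marginal_likelihood == pytest.approx(
        likelihood_given_tau(toy3, prior, 0.0), abs=1e-5
    )


def test_fit_symmetric_data_centers_on_prior_mean():
    ds = make_dataset([-0.9, 0.9, -0.3, 0.3], [0.3, 0.3, 0.5, 0.5])
    res = fit_nnhm(ds, HN, EffectPrior(0.0, 2.0))
    assert res.mu_median == pytest.approx(0.0, abs=1e-9)
    assert res.mu_mean == pytest.approx(0.0, abs=1e-9)


def test_fit_invariant_to_study_ordering(toy3):
    rev = make_dataset(list(toy3.y)[::-1], list(toy3.se)[::-1])
    a = fit_nnhm(toy3, HC)
    b = fit_nnhm(rev, HC)
    assert a.log_marginal_likelihood == pytest.approx(b.log_marginal_likelihood, abs=1e-12)
    assert a.cri_low == pytest.approx(b.cri_low, abs=1e-9)


def test_posterior_grid_and_mixture_are_normalized(toy3):
    res = fit_nnhm(toy3, HC)
    assert np.sum(res.tau_weights) == pytest.approx(1.0, abs=1e-12)
    x = np.linspace(-6, 8, 20001)
    assert np.trapezoid(res.mu_posterior.pdf(x), x) == pytest.approx(1.0, abs=1e-6)
    cdf = res.mu_posterior.cdf(x)
    assert np.all(np.diff(cdf) >= -1e-12)  # monotone 0 -> 1
    assert cdf[0] < 1e-6 and cdf[-1] > 1 - 1e-6
    assert res.extra["cri_mass"] == pytest.approx(0.95, abs=1e-6)


def test_uninformative_study_leaves_bayes_factor_unchanged(toy3):
    """Appending a study with huge se multiplies every marginal likelihood by
    (nearly) the same constant, so model ratios are unaffected."""
    big = 1e4
    aug = make_dataset(list(toy3.y) + [0.123], list(toy3.se) + [big])
    delta_hn = (
        fit_nnhm(aug, HN).log_marginal_likelihood
        - fit_nnhm(toy3, HN).log_marginal_likelihood
    )
    delta_hc = (
        fit_nnhm(aug, HC).log_marginal_likelihood
        - fit_nnhm(toy3, HC).log_marginal_likelihood
    )
    # the constant is ~ log N(y_new; 0, big^2): identical across models
    assert delta_hn == pytest.approx(delta_hc, abs=1e-6)


def test_single_study_fit_is_prior_dominated():
    ds = make_dataset([0.4], [0.5])
    res = fit_nnhm(ds, HN, EffectPrior(0.0, 2.0))
    assert res.converged
    assert 0.0 < res.mu_median < 0.4  # shrunk toward the prior mean


def test_monte_carlo_marginal_likelihood_oracle(toy3, rng):
    """Quadrature vs brute-force prior-sampling integration (10^5 draws here;
    the full 10^6-draw check lives in the acceptance suite)."""
    n = 10**5
    for prior in (HN, HC):
        if prior.family is PriorFamily.HALF_NORMAL:
            tau = np.abs(rng.normal(0.0, prior.scale, n))
        else:
            tau = np.abs(prior.scale * rng.standard_cauchy(n))
        mu = rng.normal(0.0, 2.0, n)
        var = toy3.se[None, :] ** 2 + tau[:, None] ** 2
        ll = -0.5 * np.sum(
            (toy3.y[None, :] - mu[:, None]) ** 2 / var + np.log(2 * np.pi * var), axis=1
        )
        lik = np.exp(ll)
        mc_mean = lik.mean()
        mc_se = lik.std(ddof=1) / math.sqrt(n)
        res = fit_nnhm(toy3, prior)
        assert abs(math.exp(res.log_marginal_likelihood) - mc_mean) < 3 * mc_se


# ---------------------------------------------------------------------------
# shortest interval


def test_shortest_interval_standard_normal():
    lo, hi = shortest_interval(stats.norm(0, 1), 0.95)
    z = stats.norm.ppf(0.975)
    assert lo == pytest.approx(-z, abs=1e-6)
    assert hi == pytest.approx(z, abs=1e-6)


def oracle_grid_hpd(dist, level=0.95, n=20001):
    a_grid = np.linspace(1e-9, 1 - level - 1e-9, n)
    widths = np.array([dist.ppf(a + level) - dist.ppf(a) for a in a_grid])
    i = int(np.argmin(widths))
    return dist.ppf(a_grid[i]), dist.ppf(a_grid[i] + level)


def test_shortest_interval_skewed_mixture_vs_grid_oracle():
    mix = MixtureOfNormals([0.5, 0.5], [0.0, 3.0], [1.0, 1.0])
    (lo, hi), mass, _ = shortest_interval(mix, 0.95, full_output=True)
    glo, ghi = oracle_grid_hpd(mix)
    assert lo == pytest.approx(glo, abs=1e-3)
    assert hi == pytest.approx(ghi, abs=1e-3)
    assert 0.95 <= mass <= 0.95 + 1e-6
    # strictly narrower than equal-tailed for an asymmetric density
    et = mix.ppf(0.975) - mix.ppf(0.025)
    assert hi - lo < et


def test_shortest_interval_mass_contract_right_skewed():
    dist = stats.lognorm(s=0.8)
    (lo, hi), mass, _ = shortest_interval(dist, 0.95, full_output=True)
    assert 0.95 - 1e-9 <= mass <= 0.95 + 1e-4
    glo, ghi = oracle_grid_hpd(dist)
    assert hi - lo <= (ghi - glo) + 1e-6


def test_shortest_interval_flags_multimodal_mixture():
    far = MixtureOfNormals([0.5, 0.5], [0.0, 8.0], [0.5, 0.5])
    (_, _), _, multimodal = shortest_interval(far, 0.95, full_output=True)
    assert multimodal


def test_shortest_interval_level_validation():
    with pytest.raises(ValueError):
        shortest_interval(stats.norm(), 1.2)


def test_grid_size_floor():
    ds = make_dataset([0.1], [0.5])
    with pytest.raises(ValueError):
        BayesMetaAnalysis(ds, grid_size=100)
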