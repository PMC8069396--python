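import numpy as np
import pytest
from scipy.integrate import quad

from hlowg import central_measures, entropy, quantile_shape, raw_moment
from hlowg.family import cdf, logpdf, pdf, quantile, rvs
from hlowg.properties import (
    OrderStatSpec,
    binomial_expansion_pdf,
    bonferroni_lorenz,
    incomplete_moment,
    mean_deviations,
    mgf,
    order_stat_pdf,
    pwm,
    residual_life_moment,
)

from conftest import make_params


def mc_se(values):
    return values.std(ddof=1) / np.sqrt(values.size)


# ---------------------------------------------------------------------------
# Monte Carlo oracle battery: every quadrature-based quantity is checked
# against the seeded 10^6-draw sample within 3 standard errors.
# ---------------------------------------------------------------------------

class TestMonteCarloOracles:
    def test_first_moment(self, hlowex_unit, big_unit_sample):
        x = big_unit_sample
        assert abs(raw_moment(hlowex_unit, 1) - x.mean()) < 3 * mc_se(x)

    def test_second_moment(self, hlowex_unit, big_unit_sample):
        x2 = big_unit_sample ** 2
        assert abs(raw_moment(hlowex_unit, 2) - x2.mean()) < 3 * mc_se(x2)

    def test_skewness_kurtosis(self, hlowex_unit, big_unit_sample):
        x = big_unit_sample
        rep = central_measures(hlowex_unit)
        z = (x - x.mean()) / x.std()
        sk = (z ** 3).mean()
        ku = (z ** 4).mean()
        # asymptotic standard errors of sample skewness/kurtosis
        assert abs(rep.skewness - sk) < 3 * np.sqrt(6.0 / x.size) * 4
        assert abs(rep.kurtosis - ku) < 3 * np.sqrt(24.0 / x.size) * 6

    def test_mgf(self, hlowex_unit, big_unit_sample):
        v = np.exp(0.5 * big_unit_sample)
        assert abs(mgf(hlowex_unit, 0.5) - v.mean()) < 3 * mc_se(v)

    def test_incomplete_moment_at_median(self, hlowex_unit, big_unit_sample):
        m = quantile(hlowex_unit, 0.5)
        v = big_unit_sample * (big_unit_sample <= m)
        assert abs(incomplete_moment(hlowex_unit, 1, m) - v.mean()) < 3 * mc_se(v)

    def test_lorenz(self, hlowex_unit, big_unit_sample):
        q = quantile(hlowex_unit, 0.5)
        v = big_unit_sample * (big_unit_sample <= q) / big_unit_sample.mean()
        _, L = bonferroni_lorenz(hlowex_unit, 0.5)
        assert abs(L - v.mean()) < 3 * mc_se(v)

    def test_pwm(self, hlowex_unit, big_unit_sample):
        v = big_unit_sample * cdf(hlowex_unit, big_unit_sample)
        assert abs(pwm(hlowex_unit, 1, 1) - v.mean()) < 3 * mc_se(v)

    def test_mean_residual_life_at_median(self, hlowex_unit, big_unit_sample):
        m = quantile(hlowex_unit, 0.5)
        tail = big_unit_sample[big_unit_sample > m] - m
        est = residual_life_moment(hlowex_unit, 1, m)
        assert abs(est - tail.mean()) < 3 * mc_se(tail)

    def test_reversed_residual_life(self, hlowex_unit, big_unit_sample):
        m = quantile(hlowex_unit, 0.5)
        head = m - big_unit_sample[big_unit_sample <= m]
        est = residual_life_moment(hlowex_unit, 1, m, reversed=True)
        assert abs(est - head.mean()) < 3 * mc_se(head)

    def test_shannon_entropy(self, hlowex_unit, big_unit_sample):
        v = -logpdf(hlowex_unit, big_unit_sample)
        rep = entropy(hlowex_unit, rho=2.0)
        assert abs(rep.shannon - v.mean()) < 3 * mc_se(v)

    def test_mean_deviation_about_mean(self, hlowex_unit, big_unit_sample):
        mu = raw_moment(hlowex_unit, 1)
        v = np.abs(big_unit_sample - mu)
        d_mean, _ = mean_deviations(hlowex_unit)
        assert abs(d_mean - v.mean()) < 3 * mc_se(v)


# ---------------------------------------------------------------------------
# structural identities
# ---------------------------------------------------------------------------

def test_zeroth_moment_is_one(hlowex_truth):
    assert raw_moment(hlowex_truth, 0) == 1.0


def test_negative_order_rejected(hlowex_truth):
    with pytest.raises(ValueError):
        raw_moment(hlowex_truth, -1)


def test_moment_report_identities(hlowfr_truth):
    rep = central_measures(hlowfr_truth)
    assert rep.variance >= 0
    assert rep.index_of_dispersion == pytest.approx(rep.variance / rep.mean,
                                                    rel=1e-14)
    assert rep.excess_kurtosis == pytest.approx(rep.kurtosis - 3.0)
    rep_x = central_measures(hlowfr_truth, excess=True)
    assert rep_x.kurtosis == pytest.approx(rep.kurtosis - 3.0)


def test_dispersion_labels_of_fitted_applications(hlowfr_fitted, hlowex_fitted):
    """The fitted Frechet model is over-dispersed, the fitted exponential
    model under-dispersed."""
    assert central_measures(hlowfr_fitted).index_of_dispersion > 1.0
    assert central_measures(hlowex_fitted).index_of_dispersion < 1.0


def test_mgf_basics(hlowex_truth):
    assert mgf(hlowex_truth, 0.0) == 1.0
    h = 1e-4
    deriv = (mgf(hlowex_truth, h) - mgf(hlowex_truth, -h)) / (2 * h)
    assert deriv == pytest.approx(raw_moment(hlowex_truth, 1), rel=1e-3)


def test_incomplete_moment_limits(hlowex_truth):
    top = quantile(hlowex_truth, 1 - 1e-9)
    assert incomplete_moment(hlowex_truth, 1, top) == pytest.approx(
        raw_moment(hlowex_truth, 1), rel=1e-4
    )
    assert incomplete_moment(hlowex_truth, 1, 1e-9) < 1e-6
    with pytest.raises(ValueError):
        incomplete_moment(hlowex_truth, 0, 1.0)


@pytest.mark.parametrize("case", [
    ("exponential", (1.0, 1.0, 1.0)),
    ("exponential", (1.3, 2.3, 1.5)),
    ("frechet", (1.3, 1.8, 1.5, 1.9)),
    ("weibull", (0.5, 2.0, 2.0, 1.0)),
])
def test_mean_deviation_properties(case):
    name, values = case
    p = make_params(name, values)
    d_mean, d_med = mean_deviations(p)
    assert d_mean >= 0 and d_med >= 0
    # the median minimizes E|X - c|
    assert d_med <= d_mean + 1e-10
    # brute-force oracle in x space
    mu = raw_moment(p, 1)
    lo, hi = quantile(p, 1e-10), quantile(p, 1 - 1e-10)
    direct, _ = quad(lambda x: abs(x - mu) * pdf(p, x), lo, hi,
                     points=[mu], limit=400)
    assert d_mean == pytest.approx(direct, abs=1e-6)


def test_bonferroni_lorenz_curve(hlowex_truth):
    probs = np.linspace(0.05, 0.95, 10)
    for pr in probs:
        B, L = bonferroni_lorenz(hlowex_truth, pr)
        assert 0 <= L <= pr + 1e-12  # Lorenz curve below the diagonal
        assert B == pytest.approx(L / pr)
    _, L_hi = bonferroni_lorenz(hlowex_truth, 1 - 1e-9)
    assert L_hi == pytest.approx(1.0, abs=1e-4)


def test_pwm_reductions(hlowex_truth):
    assert pwm(hlowex_truth, 2, 0) == pytest.approx(
        raw_moment(hlowex_truth, 2), abs=1e-8
    )
    for s in (0, 1, 3):
        assert pwm(hlowex_truth, 0, s) == pytest.approx(1.0 / (s + 1), abs=1e-8)


def test_residual_life_basics(hlowex_truth):
    mu = raw_moment(hlowex_truth, 1)
    # mean residual life at the origin tends to the mean
    assert residual_life_moment(hlowex_truth, 1, 1e-6) == pytest.approx(
        mu, rel=1e-4
    )
    x0 = quantile(hlowex_truth, 0.7)
    rev = residual_life_moment(hlowex_truth, 1, x0, reversed=True)
    assert 0 < rev < x0
    with pytest.raises(ValueError):
        residual_life_moment(hlowex_truth, 1, 1e9)  # cdf numerically 1


def test_quantile_shape_measures(hlowex_truth):
    sk, ku = quantile_shape(hlowex_truth)
    assert -1 < sk < 1
    # independent re-evaluation through a bisection inverse of the cdf
    from scipy.optimize import brentq

    def Q(u):
        return brentq(lambda x: cdf(hlowex_truth, x) - u, 1e-12, 1e6)

    q = {k: Q(k / 8) for k in range(1, 8)}
    assert sk == pytest.approx((q[6] + q[2] - 2 * q[4]) / (q[6] - q[2]), abs=1e-6)
    assert ku == pytest.approx(
        (q[7] - q[5] + q[3] - q[1]) / (q[6] - q[2]), abs=1e-6
    )


def test_quantile_shape_symmetric_reference():
    """The octile skewness formula returns 0 for any symmetric quantile
    function (standard normal used as the reference)."""
    from scipy.stats import norm

    q = {k: norm.ppf(k / 8) for k in range(1, 8)}
    assert (q[6] + q[2] - 2 * q[4]) / (q[6] - q[2]) == pytest.approx(0.0, abs=1e-12)


class TestEntropies:
    def test_transforms_share_one_integral(self, hlowex_truth):
        rep = entropy(hlowex_truth, rho=2.0)
        I = rep.integral_I
        assert rep.renyi == pytest.approx(np.log(I) / (1 - 2.0), rel=1e-12)
        assert rep.havrda_charvat == pytest.approx((I - 1) / (2 ** (-1.0) - 1),
                                                   rel=1e-12)
        assert rep.arimoto == pytest.approx(2.0 / (1 - 2.0) * (I ** 0.5 - 1),
                                            rel=1e-12)
        assert rep.tsallis == pytest.approx((1 - I) / (2.0 - 1), rel=1e-12)

    def test_renyi_tends_to_shannon(self, hlowex_truth):
        rep = entropy(hlowex_truth, rho=1.001)
        assert rep.renyi == pytest.approx(rep.shannon, abs=1e-2)

    def test_separate_tsallis_index(self, hlowex_truth):
        rep = entropy(hlowex_truth, rho=2.0, gamma=3.0)
        assert rep.tsallis == pytest.approx((1 - rep.integral_I) / 2.0, rel=1e-12)

    def test_rho_validation(self, hlowex_truth):
        for bad in (0.0, 1.0, -2.0):
            with pytest.raises(ValueError):
                entropy(hlowex_truth, rho=bad)


class TestOrderStatistics:
    def test_single_observation_reduces_to_pdf(self, hlowex_truth):
        x = np.array([0.3, 0.9, 1.4])
        got = order_stat_pdf(hlowex_truth, OrderStatSpec(n=1, i=1), x)
        assert np.allclose(got, pdf(hlowex_truth, x), rtol=1e-12)

    def test_median_of_five_normalizes(self, hlowex_truth):
        spec = OrderStatSpec(n=5, i=3)
        val, _ = quad(lambda x: order_stat_pdf(hlowex_truth, spec, x),
                      0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_median_of_five_against_simulation(self, hlowex_truth):
        from scipy.stats import kstest

        draws = rvs(hlowex_truth, 5 * 20_000, seed=77).reshape(20_000, 5)
        med = np.median(draws, axis=1)
        spec = OrderStatSpec(n=5, i=3)

        def F_med(x):
            x = np.atleast_1d(x)
            return np.array(
                [quad(lambda y: order_stat_pdf(hlowex_truth, spec, y),
                      0, xi, limit=200)[0] for xi in x]
            )

        grid_stat = kstest(med, F_med)
        assert grid_stat.pvalue > 0.01

    def test_rank_validation(self):
        with pytest.raises(ValueError):
            OrderStatSpec(n=5, i=0)
        with pytest.raises(ValueError):
            OrderStatSpec(n=5, i=6)


class TestBinomialExpansion:
    def test_converges_to_pdf(self):
        # convergence rate is geometric in e^{-w}, so stay away from the
        # origin where w -> 0 and the series needs many more terms
        p = make_params("exponential", (0.5, 0.8, 1.0))
        x = np.linspace(0.5, 3.0, 26)
        got = binomial_expansion_pdf(p, x, terms=200)
        assert np.allclose(got, pdf(p, x), atol=1e-10)
        assert binomial_expansion_pdf(p, 1.0, terms=200) == pytest.approx(
            float(pdf(p, 1.0)), abs=1e-10
        )

    def test_single_term(self):
        p = make_params("exponential", (0.5, 0.8, 1.0))
        x = np.array([0.4, 1.1])
        lam, beta, a = 0.5, 0.8, 1.0
        t = np.expm1(a * x)
        G, g = -np.expm1(-a * x), a * np.exp(-a * x)
        first = 2 * lam * beta * g * G ** (beta - 1) * (1 - G) ** (
            -(beta + 1)) * np.exp(-lam * t ** beta)
        assert np.allclose(binomial_expansion_pdf(p, x, terms=1), first,
                           rtol=1e-12)

    def test_alternating_series_bound(self):
        """Truncation error is bounded by the first omitted term and the
        bound shrinks monotonically."""
        p = make_params("exponential", (0.5, 0.8, 1.0))
        x = np.linspace(0.5, 2.0, 7)
        exact = pdf(p, x)
        prev_bound = None
        for terms in (3, 6, 12, 24):
            approx = binomial_expansion_pdf(p, x, terms=terms)
            omitted = np.abs(
                binomial_expansion_pdf(p, x, terms=terms + 1) - approx
            )
            assert np.all(np.abs(approx - exact) <= omitted + 1e-13)
            bound = omitted.max()
            if prev_bound is not None:
                assert bound <= prev_bound + 1e-13
            prev_bound = bound

    def test_terms_validation(self, hlowex_truth):
        with pytest.raises(ValueError):
            binomial_expansion_pdf(hlowex_truth, 1.0, terms=0)


# ---------------------------------------------------------------------------
# regression anchors: theoretical descriptives of the two fitted applications
# (frozen from this package's quadrature, cross-checked by simulation)
# ---------------------------------------------------------------------------

def test_fitted_frechet_descriptives(hlowfr_fitted):
    rep = central_measures(hlowfr_fitted)
    assert rep.mean == pytest.approx(131.277, abs=2e-3)
    assert rep.variance == pytest.approx(499.965, abs=2e-2)
    assert rep.skewness == pytest.approx(-0.5725, abs=2e-4)
    assert rep.kurtosis == pytest.approx(3.3745, abs=2e-4)
    assert rep.index_of_dispersion == pytest.approx(3.8085, abs=2e-4)


def test_fitted_exponential_descriptives(hlowex_fitted):
    rep = central_measures(hlowex_fitted)
    assert rep.mean == pytest.approx(1.5218, abs=2e-4)
    assert rep.variance == pytest.approx(0.07803, abs=2e-5)
    assert rep.skewness == pytest.approx(-1.2339, abs=2e-4)
    assert rep.kurtosis == pytest.approx(5.3093, abs=2e-4)
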