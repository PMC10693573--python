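"""Empirical distributions, Weibull model and two-sample KS machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vped.ensembles import (EmpiricalDistribution, WeibullParams,
                            build_empirical, fit_weibull, ks_two_sample,
                            pool_day_distribution, weibull_cdf, weibull_ppf)


def brute_force_ks(x1, x2):
    """Independent oracle: exhaustive sup over all union support points."""
    support = np.union1d(x1, x2)
    best = 0.0
    for s in support:
        f1 = np.mean(x1 <= s)
        f2 = np.mean(x2 <= s)
        best = max(best, abs(f1 - f2))
    return best


class TestWeibullCdf:
    def test_analytic_identities(self):
        p = WeibullParams(b=2.0, lam=3.0, gamma=1.7)
        assert weibull_cdf(2.0, p) == pytest.approx(0.0, abs=1e-12)
        assert weibull_cdf(5.0, p) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_exponential_special_case(self):
        p = WeibullParams(b=0.0, lam=4.0, gamma=1.0)
        assert weibull_cdf(4.0 * np.log(2), p) == pytest.approx(0.5, abs=1e-12)

    def test_ppf_inverts_cdf(self):
        p = WeibullParams(b=1.0, lam=2.5, gamma=0.8)
        q = np.linspace(0.01, 0.99, 21)
        assert weibull_cdf(weibull_ppf(q, p), p) == pytest.approx(q, abs=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(lam=st.floats(0.1, 50), gamma=st.floats(0.2, 5),
           b=st.floats(0, 10))
    def test_monotone_nondecreasing(self, lam, gamma, b):
        p = WeibullParams(b=b, lam=lam, gamma=gamma)
        x = np.linspace(b - 1, b + 5 * lam, 200)
        y = weibull_cdf(x, p)
        assert np.all(np.diff(y) >= -1e-12)
        assert y[0] == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WeibullParams(b=0, lam=-1, gamma=1)
        with pytest.raises(ValueError):
            WeibullParams(b=0, lam=1, gamma=0)


class TestBuildEmpirical:
    def test_step_ecdf_values(self):
        d = build_empirical([1.0, 2.0, 3.0])
        assert d.cdf(2.0) == pytest.approx(2 / 3)
        assert d.cdf(0.5) == 0.0
        assert d.cdf(3.0) == 1.0

    def test_duplicates_single_step(self):
        # brute-force counting: all mass jumps at the single support point
        d = build_empirical([2.0, 2.0, 2.0])
        assert d.cdf(1.999) == 0.0
        assert d.cdf(2.0) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            build_empirical([])

    def test_nonfinite_dropped(self):
        d = build_empirical([1.0, np.nan, 2.0, np.inf])
        assert d.n == 2

    def test_histogram_integrates_to_one(self):
        d = build_empirical(np.linspace(0, 10, 101),
                            bin_edges=np.linspace(0, 10, 11))
        edges, heights = d.histogram()
        assert np.sum(heights * np.diff(edges)) == pytest.approx(1.0)


class TestKSTwoSample:
    def test_identical_samples(self):
        d = build_empirical([1.0, 2.0, 5.0])
        r = ks_two_sample(d, d)
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_disjoint_supports(self):
        r = ks_two_sample(build_empirical([1.0, 2.0]),
                          build_empirical([10.0, 11.0]))
        assert r.statistic == 1.0

    def test_known_half_overlap(self):
        # exhaustive oracle gives D = 0.5 for [1..4] vs [3..6]
        r = ks_two_sample(build_empirical([1, 2, 3, 4]),
                          build_empirical([3, 4, 5, 6]))
        assert r.statistic == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(1, 9, size=2)
            x1 = np.round(rng.uniform(0, 5, n1), 1)
            x2 = np.round(rng.uniform(0, 5, n2), 1)
            r = ks_two_sample(build_empirical(x1), build_empirical(x2))
            assert r.statistic == pytest.approx(brute_force_ks(x1, x2),
                                                abs=1e-12)

    def test_symmetry(self, rng):
        d1 = build_empirical(rng.normal(size=40))
        d2 = build_empirical(rng.normal(0.3, size=30))
        r12, r21 = ks_two_sample(d1, d2), ks_two_sample(d2, d1)
        assert r12.statistic == r21.statistic
        assert r12.pvalue == r21.pvalue

    def test_agrees_with_scipy_on_unweighted(self, rng):
        from scipy import stats
        x1 = rng.weibull(1.3, 80)
        x2 = rng.weibull(1.6, 60)
        r = ks_two_sample(build_empirical(x1), build_empirical(x2))
        assert r.statistic == pytest.approx(
            stats.ks_2samp(x1, x2).statistic, abs=1e-12)


class TestFitWeibull:
    def test_recovers_known_parameters(self):
        errs_g, errs_l = [], []
        for seed in range(15):
            x = 5.0 * np.random.default_rng(seed).weibull(1.5, 2000)
            p = fit_weibull(build_empirical(x), location_policy=0.0)
            errs_g.append(abs(p.gamma - 1.5))
            errs_l.append(abs(p.lam - 5.0) / 5.0)
        assert np.median(errs_g) <= 0.1
        assert np.median(errs_l) <= 0.08

    def test_exponential_shape(self):
        x = np.random.default_rng(3).exponential(2.0, 2000)
        p = fit_weibull(build_empirical(x), location_policy=0.0)
        assert 0.9 <= p.gamma <= 1.1

    def test_bias_shrinks_with_n(self):
        def bias(n):
            errs = [fit_weibull(build_empirical(
                2.0 * np.random.default_rng(s).weibull(0.9, n)),
                location_policy=0.0).gamma - 0.9 for s in range(30)]
            return abs(np.mean(errs))
        assert bias(2000) <= max(bias(200) / 2, 0.01)

    def test_self_consistency_sup_distance(self):
        x = 5.0 * np.random.default_rng(9).weibull(1.5, 2000)
        p = fit_weibull(build_empirical(x), location_policy=0.0)
        assert p.sup_distance < 0.05

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            fit_weibull(build_empirical(np.full(50, 3.0)))

    def test_fixed_location_below_values_raises(self):
        with pytest.raises(ValueError):
            fit_weibull(build_empirical(np.linspace(1, 2, 50)),
                        location_policy=1.5)


class TestPooling:
    def test_single_and_identical_samples_fixed_point(self):
        edges = np.linspace(0, 10, 11)
        d = build_empirical(np.linspace(0.5, 9.5, 100), feature="f",
                            bin_edges=edges)
        pooled1 = pool_day_distribution([d])
        pooled2 = pool_day_distribution([d, d])
        _, h = d.histogram()
        _, h1 = pooled1.histogram()
        _, h2 = pooled2.histogram()
        assert h1 == pytest.approx(h)
        assert h2 == pytest.approx(h)

    def test_count_weighting(self):
        # n=100 at one bin, n=300 at another -> 0.25/0.75 mass split
        edges = np.array([0.0, 1.0, 2.0])
        a = build_empirical(np.full(100, 0.5), feature="f", bin_edges=edges)
        b = build_empirical(np.full(300, 1.5), feature="f", bin_edges=edges)
        _, h = pool_day_distribution([a, b]).histogram(edges)
        mass = h * np.diff(edges)
        assert mass == pytest.approx([0.25, 0.75])

    def test_incompatible_features_raise(self):
        a = build_empirical([1.0, 2.0], feature="x")
        b = build_empirical([1.0, 2.0], feature="y")
        with pytest.raises(ValueError):
            pool_day_distribution([a, b])
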