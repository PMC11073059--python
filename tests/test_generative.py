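import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from _stat_utils import allocation_class_multiplicity, pool_and_chisquare
from sbsp import (
    FeatureFrequencies,
    SBSPParams,
    draw_total_mass_posterior,
    draw_total_mass_prior,
    gamma0,
    log_efpf,
    negbin_pmf,
    powerlaw_probabilities,
    simulate_continuation,
    simulate_fixed_probabilities,
    simulate_forward,
    split_rows,
    sufficient_stats,
    true_unseen,
    unseen_point_estimate,
    unseen_posterior,
)


class TestTotalMass:
    def test_prior_exponential_corner(self):
        rng = np.random.default_rng(0)
        draws = [draw_total_mass_prior(SBSPParams(0.5, 0.0, 1.0), rng) for _ in range(10**5)]
        assert np.mean(draws) == pytest.approx(1.0, abs=0.02)

    def test_prior_gamma_mean(self):
        rng = np.random.default_rng(1)
        draws = [draw_total_mass_prior(SBSPParams(0.5, 3.0, 2.0), rng) for _ in range(10**5)]
        assert np.mean(draws) == pytest.approx(4 / 2, rel=0.02)

    def test_prior_deterministic(self):
        p = SBSPParams(0.5, 1.0, 1.0)
        assert draw_total_mass_prior(p, 7) == draw_total_mass_prior(p, 7)

    def test_posterior_reduces_to_prior(self, empty_stats):
        p = SBSPParams(0.5, 1.0, 2.0)
        assert draw_total_mass_posterior(p, empty_stats, 3) == draw_total_mass_prior(p, 3)

    def test_posterior_mean(self):
        p = SBSPParams(0.4, 2.0, 1.0)
        stats = FeatureFrequencies(n=10, k=5, m=[1] * 5)
        rng = np.random.default_rng(2)
        draws = [draw_total_mass_posterior(p, stats, rng) for _ in range(10**5)]
        expected = (5 + 2 + 1) / (1 + gamma0(10, 0.4))
        assert np.mean(draws) == pytest.approx(expected, rel=0.02)

    def test_largest_atom_change_of_variables(self):
        # Delta_1 = T^(-1/sigma); its cdf is the Gamma survival function at
        # a^(-sigma), cross-checked against quadrature of the closed-form density
        p = SBSPParams(0.5, 1.0, 2.0)
        stats = FeatureFrequencies(n=6, k=3, m=[1, 2, 3])
        rate = p.beta + gamma0(6, p.sigma)
        shape = 3 + p.c + 1
        rng = np.random.default_rng(3)
        delta = np.array(
            [draw_total_mass_posterior(p, stats, rng) for _ in range(5000)]
        ) ** (-1 / p.sigma)

        def density(a):
            return (
                p.sigma
                * rate**shape
                / math.gamma(shape)
                * a ** (-3 * p.sigma - (p.c + 1) * p.sigma - 1)
                * np.exp(-(a**-p.sigma) * rate)
            )

        from scipy.integrate import quad

        def cdf(a):
            if np.isscalar(a):
                return quad(density, 0, a)[0]
            return np.array([quad(density, 0, ai)[0] for ai in a])

        # quadrature oracle agrees with the analytic change of variables
        for a in (0.05, 0.2, 1.0):
            assert cdf(a) == pytest.approx(
                gamma_dist(shape, scale=1 / rate).sf(a**-p.sigma), rel=1e-6
            )
        assert kstest(delta, cdf).pvalue > 0.01


class TestSimulateForward:
    def test_n_zero(self):
        mat = simulate_forward(SBSPParams(0.5, 1.0, 1.0), 0, seed=0)
        assert mat.n_samples == 0
        assert mat.n_features == 0

    def test_deterministic(self):
        p = SBSPParams(0.5, 1.0, 2.0)
        a = simulate_forward(p, 30, seed=5)
        b = simulate_forward(p, 30, seed=5)
        np.testing.assert_array_equal(a.incidence, b.incidence)

    def test_state_invariants(self):
        mat, state = simulate_forward(
            SBSPParams(0.5, 1.0, 2.0), 25, seed=8, return_state=True
        )
        state.validate()
        assert state.n_done == 25
        assert len(state.features) == mat.n_features + mat.n_dropped

    def test_k_marginal_chisquare_smoke(self):
        # K_n ~ NegBin(c+1, gamma0(n)/(beta+gamma0(n))): headline contract
        p = SBSPParams(0.5, 1.0, 2.0)
        n, reps = 20, 4000
        rng = np.random.default_rng(12)
        ks = np.array([simulate_forward(p, n, rng).n_features for _ in range(reps)])
        law = unseen_posterior(p, FeatureFrequencies(n=0, k=0, m=[]), n)
        support = np.arange(ks.max() + 1)
        probs = [negbin_pmf(law, int(u)) for u in support]
        pval = pool_and_chisquare(np.bincount(ks), probs)
        assert pval > 0.01

    def test_singleton_allocation_frequency(self, toy_params):
        # P(k=1, m=(1)) at n=1 equals exp(log_efpf) = 0.25
        reps = 20000
        rng = np.random.default_rng(21)
        hits = sum(
            1
            for _ in range(reps)
            if simulate_forward(toy_params, 1, rng).n_features == 1
        )
        se = np.sqrt(0.25 * 0.75 / reps)
        assert abs(hits / reps - 0.25) < 3 * se

    def test_allocation_classes_match_efpf_n2(self, toy_params):
        reps = 20000
        rng = np.random.default_rng(30)
        from collections import Counter

        counts = Counter()
        for _ in range(reps):
            stats = sufficient_stats(simulate_forward(toy_params, 2, rng))
            counts[tuple(sorted(stats.m))] += 1
        for cls in [(), (1,), (2,), (1, 1), (1, 2)]:
            stats = FeatureFrequencies(n=2, k=len(cls), m=list(cls))
            prob = np.exp(log_efpf(toy_params, stats)) * allocation_class_multiplicity(
                2, cls
            )
            se = np.sqrt(prob * (1 - prob) / reps)
            assert abs(counts[cls] / reps - prob) < 3 * se + 1e-12

    def test_recurrence_probability(self):
        # feature with count m in first j samples recurs in sample j+1 with
        # probability (m - sigma)/(j + 1 - sigma)
        sigma = 0.5
        p = SBSPParams(sigma, 1.0, 2.0)
        j = 3
        rng = np.random.default_rng(40)
        hits = {1: 0, 2: 0, 3: 0}
        totals = {1: 0, 2: 0, 3: 0}
        for _ in range(4000):
            mat = simulate_forward(p, j + 1, rng)
            arr = mat.incidence
            m_first = arr[:j].sum(axis=0)
            for col in range(arr.shape[1]):
                m = int(m_first[col])
                if m >= 1:
                    totals[m] += 1
                    hits[m] += int(arr[j, col])
        for m in (1, 2, 3):
            expected = (m - sigma) / (j + 1 - sigma)
            se = np.sqrt(expected * (1 - expected) / totals[m])
            assert abs(hits[m] / totals[m] - expected) < 4 * se


class TestSimulateContinuation:
    def test_prevalence_sums_to_total(self):
        stats = FeatureFrequencies(n=10, k=5, m=[1, 1, 2, 3, 10])
        draws = simulate_continuation(stats, SBSPParams(0.5, 1.0, 2.0), 8, 200, seed=0)
        assert len(draws) == 200
        for d in draws:
            assert sum(d.by_prevalence.values()) == d.u_total
            assert all(1 <= r <= 8 for r in d.by_prevalence)

    def test_total_law_chisquare_smoke(self):
        p = SBSPParams(0.5, 1.0, 2.0)
        stats = FeatureFrequencies(n=5, k=3, m=[1, 2, 3])
        m_extra, reps = 10, 4000
        draws = simulate_continuation(stats, p, m_extra, reps, seed=14)
        u = np.array([d.u_total for d in draws])
        law = unseen_posterior(p, stats, m_extra)
        probs = [negbin_pmf(law, int(v)) for v in range(u.max() + 1)]
        assert pool_and_chisquare(np.bincount(u), probs) > 0.01

    def test_single_step_mean_matches_estimate(self):
        p = SBSPParams(0.6, 0.5, 1.0)
        stats = FeatureFrequencies(n=8, k=4, m=[1, 1, 2, 8])
        draws = simulate_continuation(stats, p, 1, 20000, seed=15)
        mean = np.mean([d.u_total for d in draws])
        expected = unseen_point_estimate(p, stats, 1)
        assert mean == pytest.approx(expected, rel=0.05)

    def test_deterministic(self):
        stats = FeatureFrequencies(n=4, k=2, m=[1, 2])
        p = SBSPParams(0.5, 1.0, 1.0)
        a = simulate_continuation(stats, p, 5, 50, seed=9)
        b = simulate_continuation(stats, p, 5, 50, seed=9)
        assert a == b


class TestFixedProbabilities:
    def test_near_one_probabilities(self):
        mat = simulate_fixed_probabilities([1 - 1e-12] * 5, 3, seed=0)
        assert mat.n_features == 5
        assert mat.column_sums().tolist() == [3] * 5

    def test_domain(self):
        with pytest.raises(ValueError):
            simulate_fixed_probabilities([0.5, 1.0], 3, seed=0)
        with pytest.raises(ValueError):
            simulate_fixed_probabilities([0.0], 3, seed=0)

    def test_expected_distinct_count(self):
        p = np.array([0.5, 0.1, 0.01])
        n, reps = 10, 10000
        rng = np.random.default_rng(3)
        ks = [simulate_fixed_probabilities(p, n, rng).n_features for _ in range(reps)]
        expected = np.sum(1 - (1 - p) ** n)
        var = np.sum((1 - (1 - p) ** n) * (1 - p) ** n)
        assert abs(np.mean(ks) - expected) < 3 * np.sqrt(var / reps)

    def test_expected_true_unseen(self):
        p = np.full(40, 0.05)
        n_train, n_test, reps = 5, 10, 2000
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(reps):
            mat = simulate_fixed_probabilities(p, n_train + n_test, rng)
            train, test = split_rows(mat, n_train, rng)
            vals.append(true_unseen(train, test))
        expected = np.sum((1 - p) ** n_train * (1 - (1 - p) ** n_test))
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)


class TestPowerlawProbabilities:
    def test_direct_formula(self):
        np.testing.assert_allclose(
            powerlaw_probabilities(3, 1.0, 0.5), [0.5, 0.25, 1 / 6], rtol=1e-12
        )

    def test_monotone_nonincreasing(self):
        p = powerlaw_probabilities(100, 1.7, 0.9)
        assert np.all(np.diff(p) <= 0)
        assert np.all((p > 0) & (p < 1))

    def test_zero_exponent_constant(self):
        np.testing.assert_allclose(powerlaw_probabilities(4, 0.0, 0.3), [0.3] * 4)

    def test_domain(self):
        with pytest.raises(ValueError):
            powerlaw_probabilities(0, 1.0, 0.5)
        with pytest.raises(ValueError):
            powerlaw_probabilities(3, 1.0, 1.5)
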