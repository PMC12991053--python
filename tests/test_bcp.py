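"""The changepoint model: sufficient statistics, conditional odds, the Gibbs
sweep and the full chain, against closed forms and the enumeration oracle."""

import numpy as np
import pytest

from cnaseg.bcp import (
    BCPHyperparameters,
    MCMCSettings,
    Partition,
    block_statistics,
    conditional_odds,
    conditional_posterior_means,
    gibbs_sweep,
    run_bcp,
)
from cnaseg.oracle import exact_posterior


def partition_with_cuts(n, indicator_indices):
    ind = np.zeros(n, dtype=np.int8)
    ind[list(indicator_indices)] = 1
    ind[n - 1] = 1
    return Partition(ind)


class TestBlockStatistics:
    def test_two_level_example(self):
        b, W, B = block_statistics([1, 1, 5, 5], partition_with_cuts(4, [1]))
        assert b == 2
        assert W == pytest.approx(0.0)
        assert B == pytest.approx(16.0)

    def test_constant_data_zero_sums(self, rng):
        for _ in range(5):
            cuts = np.flatnonzero(rng.random(7) < 0.4)
            b, W, B = block_statistics([2.0] * 8, partition_with_cuts(8, cuts))
            assert W == pytest.approx(0.0)
            assert B == pytest.approx(0.0, abs=1e-12)

    def test_anova_identity(self, rng):
        x = rng.normal(size=10)
        cuts = np.flatnonzero(rng.random(9) < 0.3)
        _, W, B = block_statistics(x, partition_with_cuts(10, cuts))
        tss = np.sum((x - x.mean()) ** 2)
        assert W + B == pytest.approx(tss, rel=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            block_statistics([1.0, 2.0, 3.0], partition_with_cuts(4, []))


class TestConditionalOdds:
    def test_boundary_dominates_interior(self):
        x = np.array([0.0] * 4 + [10.0] * 4)
        rho = partition_with_cuts(8, [])
        at_boundary = conditional_odds(x, rho, 3)
        interior = [conditional_odds(x, rho, i) for i in (0, 1, 5, 6)]
        assert all(at_boundary > 100 * o for o in interior)

    def test_constant_data_exchangeable(self):
        # under constant data and a symmetric conditioning partition, every
        # free position has identical odds (= the prior odds)
        x = np.full(9, 3.25)
        rho = partition_with_cuts(9, [])
        odds = [conditional_odds(x, rho, i) for i in range(8)]
        assert np.allclose(odds, odds[0])

    def test_position_bounds_enforced(self):
        x = np.arange(5.0)
        rho = partition_with_cuts(5, [])
        with pytest.raises(ValueError):
            conditional_odds(x, rho, 4)  # the forced final changepoint
        with pytest.raises(ValueError):
            conditional_odds(x, rho, -1)

    def test_agrees_with_enumeration_ratio(self, rng):
        """Odds must equal the ratio of exact conditional probabilities."""
        x = rng.normal(size=6)
        x[3:] += 1.5
        hyper = BCPHyperparameters(p0=0.3, w0=0.2)
        # enumerate both configurations at position 2 with others fixed
        base = partition_with_cuts(6, [4])
        odds = conditional_odds(x, base, 2, hyper)
        from cnaseg.oracle import _log_prior_exact, _log_w_exact

        def log_weight(cuts):
            rho = partition_with_cuts(6, cuts)
            b, W, B = block_statistics(x, rho)
            prior = _log_prior_exact(6, hyper.p0)
            return prior[b] + _log_w_exact(6, b, W, B, hyper.w0, 1e-12)

        expected = np.exp(log_weight([2, 4]) - log_weight([4]))
        assert odds == pytest.approx(expected, rel=1e-6)


class TestGibbsSweep:
    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=30)
        rho = partition_with_cuts(30, [10])
        out1 = gibbs_sweep(x, rho, rng=np.random.default_rng(7))
        out2 = gibbs_sweep(x, rho, rng=np.random.default_rng(7))
        assert np.array_equal(out1.indicators, out2.indicators)

    def test_constant_data_tiny_p0_stays_empty(self):
        x = np.full(40, 1.5)
        rho = Partition.empty(40)
        out = gibbs_sweep(x, rho, BCPHyperparameters(p0=1e-6), np.random.default_rng(1))
        assert out.indicators[:-1].sum() == 0
        assert out.indicators[-1] == 1

    def test_preserves_final_changepoint(self, rng):
        x = rng.normal(size=25)
        out = gibbs_sweep(x, Partition.empty(25), rng=rng)
        assert out.indicators[-1] == 1


class TestConditionalPosteriorMeans:
    def test_two_block_levels_ordered(self):
        x = np.array([1.0, 1.0, 9.0, 9.0])
        out = conditional_posterior_means(x, partition_with_cuts(4, [1]))
        assert out[0] == out[1] < out[2] == out[3]

    def test_single_block_is_grand_mean(self, rng):
        x = rng.normal(size=12)
        out = conditional_posterior_means(x, Partition.empty(12))
        assert np.allclose(out, x.mean())

    def test_reduces_to_block_means_as_w0_vanishes(self, rng):
        x = rng.normal(size=10)
        x[5:] += 3.0
        rho = partition_with_cuts(10, [4])
        out = conditional_posterior_means(x, rho, BCPHyperparameters(w0=1e-9))
        assert np.allclose(out[:5], x[:5].mean(), atol=1e-6)
        assert np.allclose(out[5:], x[5:].mean(), atol=1e-6)

    def test_shrinks_toward_grand_mean(self, rng):
        x = rng.normal(size=16)
        x[8:] += 2.0
        rho = partition_with_cuts(16, [7])
        shrunk = conditional_posterior_means(x, rho, BCPHyperparameters(w0=0.9))
        g = x.mean()
        assert abs(shrunk[0] - g) < abs(x[:8].mean() - g)


class TestRunBcp:
    def test_localizes_boundary(self, two_level_x):
        res = run_bcp(two_level_x, settings=MCMCSettings(seed=3))
        assert abs(int(np.argmax(res.posterior_prob[:-1])) - 99) <= 2

    def test_bitwise_deterministic(self, rng):
        x = rng.normal(size=60)
        r1 = run_bcp(x, settings=MCMCSettings(burnin=100, m=300, seed=11))
        r2 = run_bcp(x, settings=MCMCSettings(burnin=100, m=300, seed=11))
        assert np.array_equal(r1.posterior_prob, r2.posterior_prob)
        assert np.array_equal(r1.posterior_mean, r2.posterior_mean)
        assert np.array_equal(r1.ci_lower, r2.ci_lower)
        assert np.array_equal(r1.ci_upper, r2.ci_upper)

    def test_probability_bounds_and_forced_end(self, rng):
        x = rng.normal(size=50)
        res = run_bcp(x, settings=MCMCSettings(burnin=50, m=200, seed=5))
        assert np.all(res.posterior_prob >= 0.0)
        assert np.all(res.posterior_prob <= 1.0)
        assert res.posterior_prob[-1] == 1.0
        assert np.all(res.ci_lower <= res.ci_upper + 1e-12)

    def test_shift_invariance(self, rng):
        """Adding a constant leaves the changepoint posterior unchanged (the
        grand mean is integrated out) and shifts the posterior mean."""
        x = rng.normal(size=40)
        x[20:] += 1.0
        r1 = run_bcp(x, settings=MCMCSettings(burnin=100, m=500, seed=9))
        r2 = run_bcp(x + 7.5, settings=MCMCSettings(burnin=100, m=500, seed=9))
        assert np.array_equal(r1.posterior_prob, r2.posterior_prob)
        assert np.allclose(r2.posterior_mean, r1.posterior_mean + 7.5, atol=1e-9)

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            run_bcp(np.array([1.0]))


class TestExactPosterior:
    def test_n2_two_term_direct(self):
        """n = 2 has a single free indicator; check against the explicit
        two-partition computation with scipy quadrature."""
        from scipy import integrate

        x = np.array([0.3, 1.1])
        hyper = BCPHyperparameters(p0=0.4, w0=0.3)
        prob, _ = exact_posterior(x, hyper)
        n = 2
        tss = np.sum((x - x.mean()) ** 2)

        def w_int(b, W, B):
            val, _ = integrate.quad(
                lambda w: w ** (b / 2) * (W + B * w) ** (-(n - 1) / 2),
                0, hyper.w0,
            )
            return val

        def p_int(b):
            val, _ = integrate.quad(
                lambda p: p ** b * (1 - p) ** (n - b - 1), 0, hyper.p0
            )
            return val

        w_split = p_int(2) * w_int(2, 0.0, tss)  # two singleton blocks: W=0
        w_merged = p_int(1) * w_int(1, tss, 0.0)  # one block: B=0
        assert prob[0] == pytest.approx(w_split / (w_split + w_merged), rel=1e-6)

    def test_constant_data_symmetric(self):
        prob, mean = exact_posterior(np.full(7, 2.0))
        assert np.allclose(prob[:-1], prob[0])
        assert np.allclose(mean, 2.0)

    def test_reversal_symmetry(self, rng):
        """Reversing the data reverses the interior probability vector:
        indicator i (boundary after bin i) maps to indicator n-2-i."""
        x = rng.normal(size=9)
        x[5:] += 1.0
        p_fwd, m_fwd = exact_posterior(x)
        p_rev, m_rev = exact_posterior(x[::-1])
        assert np.allclose(p_rev[:-1], p_fwd[:-1][::-1], atol=1e-9)
        assert np.allclose(m_rev, m_fwd[::-1], atol=1e-9)

    def test_shift_invariance_exact(self, rng):
        x = rng.normal(size=8)
        p1, m1 = exact_posterior(x)
        p2, m2 = exact_posterior(x + 100.0)
        assert np.allclose(p1, p2, atol=1e-8)
        assert np.allclose(m2, m1 + 100.0, atol=1e-7)

    def test_zero_noise_concentrates_on_truth(self):
        x = np.array([0.0] * 5 + [5.0] * 5)
        prob, mean = exact_posterior(x)
        assert prob[4] == pytest.approx(1.0)
        assert np.max(np.delete(prob[:-1], 4)) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(mean, x)

    def test_size_cap(self, rng):
        with pytest.raises(ValueError):
            exact_posterior(rng.normal(size=15))


def test_mean_consistency_enumeration_vs_conditional_means(rng):
    """The enumeration-weighted average of per-partition conditional means
    must reproduce the exact posterior mean (n = 6)."""
    x = rng.normal(size=6)
    x[3:] += 2.0
    hyper = BCPHyperparameters(p0=0.3, w0=0.2)
    _, exact_mean = exact_posterior(x, hyper)
    res = run_bcp(x, hyper, MCMCSettings(burnin=500, m=4000, thin=5, seed=13))
    assert np.allclose(res.posterior_mean, exact_mean, atol=0.03)
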