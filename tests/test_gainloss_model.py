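import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import phylocoev as pc
from phylocoev.gainloss_model import (ModelError, log_p_all_zero,
                                      _gamma_category_multipliers)
from _oracles import enumerate_site_likelihood, random_binary_phylogeny


class TestTransitionProbability:
    def test_identity_at_t0(self):
        assert np.allclose(pc.transition_probability(2.0, 0.7, 0.0), np.eye(2))

    def test_closed_form_value(self):
        P = pc.transition_probability(1.0, 1.0, 0.5)
        assert P[0, 1] == pytest.approx(0.5 * (1 - math.exp(-1.0)), abs=1e-7)
        assert P[0, 1] == pytest.approx(0.3160603, abs=1e-7)

    def test_stationary_limit(self):
        P = pc.transition_probability(2.0, 1.0, 1e6)
        pi = pc.stationary_frequencies(2.0, 1.0)
        assert np.allclose(P[0], pi) and np.allclose(P[1], pi)

    def test_negative_time_rejected(self):
        with pytest.raises(ModelError):
            pc.transition_probability(1.0, 1.0, -0.1)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            g, l, t = rng.random(3) * 3 + 0.01
            assert np.allclose(pc.transition_probability(g, l, t).sum(axis=1), 1.0)

    @given(g=st.floats(1e-3, 5.0), l=st.floats(1e-3, 5.0),
           t1=st.floats(0.0, 3.0), t2=st.floats(0.0, 3.0))
    def test_semigroup_property_hypothesis(self, g, l, t1, t2):
        P12 = pc.transition_probability(g, l, t1) @ pc.transition_probability(g, l, t2)
        assert np.max(np.abs(P12 - pc.transition_probability(g, l, t1 + t2))) < 1e-11
        assert np.all(P12 >= 0) and np.allclose(P12.sum(axis=1), 1.0)

    def test_chapman_kolmogorov_and_detailed_balance(self, rng):
        for _ in range(200):
            g, l = rng.random(2) * 3 + 1e-3
            t1, t2 = rng.random(2) * 2
            P1 = pc.transition_probability(g, l, t1)
            P2 = pc.transition_probability(g, l, t2)
            P12 = pc.transition_probability(g, l, t1 + t2)
            assert np.max(np.abs(P1 @ P2 - P12)) < 1e-12
            pi0, pi1 = pc.stationary_frequencies(g, l)
            assert abs(pi0 * P1[0, 1] - pi1 * P1[1, 0]) < 1e-12


class TestStationaryFrequencies:
    def test_hand_value(self):
        assert pc.stationary_frequencies(2.0, 1.0) == pytest.approx((1 / 3, 2 / 3))

    def test_symmetry(self):
        assert pc.stationary_frequencies(0.7, 0.7) == (0.5, 0.5)

    def test_sums_to_one(self, rng):
        for _ in range(10):
            g, l = rng.random(2) + 1e-3
            assert sum(pc.stationary_frequencies(g, l)) == pytest.approx(1.0)


class TestRateMixture:
    def test_single_tier_one_category(self):
        mix = pc.build_rate_mixture(pc.GainLossParams(g=1.0, l=1.0, model_tier="single"))
        assert mix.n_categories == 1
        assert mix.mean_total_rate() == pytest.approx(1.0)

    def test_large_alpha_concentrates_at_mean(self):
        # bin means of Gamma(alpha, mean 1) spread ~ +-1.27/sqrt(alpha)
        assert np.allclose(_gamma_category_multipliers(1e6, 4), 1.0, atol=2e-3)
        assert np.allclose(_gamma_category_multipliers(1e8, 4), 1.0, atol=2e-4)

    def test_gamma_invariant_weights_and_categories(self):
        params = pc.GainLossParams(g=1.0, l=1.0, model_tier="gamma_invariant",
                                   alpha=0.8, p_inv=0.2, K=4)
        mix = pc.build_rate_mixture(params)
        assert mix.n_categories == 5
        assert np.allclose(mix.weights, 0.2)
        assert mix.gains[-1] == 0.0 and mix.losses[-1] == 0.0
        assert mix.mean_total_rate() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha,K", [(0.5, 4), (1.0, 4), (2.3, 6)])
    def test_quantile_discretization_against_numerical_integration(self, alpha, K):
        """Category multipliers equal conditional bin means of Gamma(alpha,
        mean 1), computed here by direct numerical integration."""
        mult = _gamma_category_multipliers(alpha, K)
        edges = gamma_dist.ppf(np.linspace(0, 1, K + 1), a=alpha, scale=1 / alpha)
        for k in range(K):
            num, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                          edges[k], min(edges[k + 1], 1e3))
            assert mult[k] == pytest.approx(num * K, rel=1e-5)
        assert mult.mean() == pytest.approx(1.0, rel=1e-9)

    def test_mixture_tier_grid(self):
        params = pc.GainLossParams(g=1.0, l=2.0, model_tier="mixture",
                                   alpha_gain=0.7, alpha_loss=1.5,
                                   K_gain=3, K_loss=3)
        mix = pc.build_rate_mixture(params)
        assert mix.n_categories == 9
        assert mix.weights.sum() == pytest.approx(1.0)
        assert mix.mean_total_rate() == pytest.approx(1.0)

    def test_invalid_category_count_rejected(self):
        with pytest.raises(ModelError):
            pc.GainLossParams(K=0)


class TestSiteLikelihood:
    def test_two_leaf_worked_example(self, two_leaf_tree, unit_mix):
        L = pc.site_likelihood(two_leaf_tree, [0, 1], unit_mix, taxa=["A", "B"])
        p01 = 0.5 * (1 - math.exp(-1.0))
        assert L == pytest.approx(2 * 0.5 * (1 - p01) * p01, abs=1e-10)

    def test_pruning_equals_enumeration(self, rng):
        """Felsenstein pruning matches the brute-force sum over interior
        state assignments, including under a gamma+invariant mixture."""
        mix = pc.build_rate_mixture(pc.GainLossParams(
            g=1.3, l=0.8, model_tier="gamma_invariant", alpha=0.9, p_inv=0.15, K=3))
        for _ in range(30):
            n = int(rng.integers(3, 7))
            tree = random_binary_phylogeny(n, rng)
            col = rng.integers(0, 2, n)
            L = pc.site_likelihood(tree, col, mix, taxa=tree.leaf_labels)
            L_ref = enumerate_site_likelihood(tree, col, mix)
            assert abs(L - L_ref) < 1e-12

    def test_zero_length_star_all_ones(self):
        tree = pc.Phylogeny([-1, 0, 0, 0], [0, 0, 0, 0], [None, "A", "B", "C"])
        mix = pc.build_rate_mixture(pc.GainLossParams(
            g=2.0, l=1.0, model_tier="gamma_invariant", alpha=1.0, p_inv=0.3, K=2))
        L = pc.site_likelihood(tree, [1, 1, 1], mix)
        expected = float(mix.weights @ mix.pis[:, 1])
        assert L == pytest.approx(expected, abs=1e-12)

    def test_root_placement_invariance(self, unit_mix):
        """Reversibility: the same unrooted tree rooted differently gives
        identical likelihoods."""
        t1 = pc.Phylogeny.from_newick("((A:0.2,B:0.4):0.3,(C:0.1,D:0.6):0.2);")
        t2 = pc.Phylogeny.from_newick("(A:0.2,(B:0.4),((C:0.1,D:0.6):0.5));")
        # same unrooted tree: root moved onto A's branch end
        t2 = pc.Phylogeny.from_newick("(A:0.1,(B:0.4,((C:0.1,D:0.6):0.5):0.0):0.1);")
        for col in ([0, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 1]):
            L1 = pc.site_likelihood(t1, col, unit_mix, taxa=list("ABCD"))
            L2 = pc.site_likelihood(t2, col, unit_mix, taxa=list("ABCD"))
            assert L1 == pytest.approx(L2, abs=1e-12)

    def test_leaf_mismatch_rejected(self, two_leaf_tree, unit_mix):
        with pytest.raises(ModelError):
            pc.site_likelihood(two_leaf_tree, [0, 1], unit_mix, taxa=["A", "X"])


class TestCorrectedLikelihood:
    def test_two_leaf_correction_worked_example(self, two_leaf_tree, unit_mix):
        pat = pc.PhyleticPattern(taxa=["A", "B"], characters=["c"],
                                 matrix=[[0], [1]])
        res = pc.corrected_log_likelihood(two_leaf_tree, pat, unit_mix,
                                          correction="no_absent")
        p00 = 0.5 * (1 + math.exp(-1.0)) / 2 + 0.5 * (1 - math.exp(-1.0)) / 2
        p_all0 = 0.5 * ((0.5 * (1 + math.exp(-1.0))) ** 2
                        + (0.5 * (1 - math.exp(-1.0))) ** 2)
        L = 2 * 0.5 * (0.5 * (1 + math.exp(-1.0))) * (0.5 * (1 - math.exp(-1.0)))
        assert math.exp(res.log_p_unobservable) == pytest.approx(p_all0, abs=1e-10)
        assert math.exp(res.log_likelihood) == pytest.approx(L / (1 - p_all0), abs=1e-10)

    def test_none_correction_is_plain_sum(self, tree8, unit_mix, small_pattern):
        res = pc.corrected_log_likelihood(tree8, small_pattern, unit_mix,
                                          correction="none")
        assert res.log_likelihood == pytest.approx(
            res.per_site_log_likelihood.sum())

    def test_correction_never_decreases_likelihood(self, tree8, unit_mix,
                                                   small_pattern):
        plain = pc.corrected_log_likelihood(tree8, small_pattern, unit_mix, "none")
        corr = pc.corrected_log_likelihood(tree8, small_pattern, unit_mix,
                                           "no_absent")
        assert corr.log_likelihood >= plain.log_likelihood

    def test_posterior_category_rows_sum_to_one(self, tree8, small_pattern):
        mix = pc.build_rate_mixture(pc.GainLossParams(
            model_tier="gamma_invariant", alpha=0.7, p_inv=0.1, K=4))
        res = pc.corrected_log_likelihood(tree8, small_pattern, mix)
        assert np.allclose(res.posterior_category_weights.sum(axis=1), 1.0)


class TestFitModel:
    def test_recovers_ratio_and_beats_truth(self, bench_mix):
        tree = pc.random_phylogeny(32, seed=3)
        true_params = pc.GainLossParams(g=2.0, l=1.0, model_tier="single")
        mix_true = pc.build_rate_mixture(true_params)
        pat = pc.simulate_independent_sites(tree, mix_true, 600, seed=4)
        params, res = pc.fit_model(tree, pat, tier="single")
        assert params.ratio == pytest.approx(2.0, rel=0.25)
        truth_ll = pc.corrected_log_likelihood(tree, pat, mix_true).log_likelihood
        assert res.log_likelihood >= truth_ll - 1e-6

    def test_gamma_invariant_nests_single(self):
        """On single-rate data the richer model cannot do worse, and should
        not do meaningfully better (nested models)."""
        tree = pc.random_phylogeny(16, seed=5, total_length=4.0)
        mix_true = pc.build_rate_mixture(pc.GainLossParams(g=1.0, l=1.0,
                                                           model_tier="single"))
        pat = pc.simulate_independent_sites(tree, mix_true, 300, seed=6)
        _, res_single = pc.fit_model(tree, pat, tier="single")
        _, res_gi = pc.fit_model(tree, pat, tier="gamma_invariant", K=4)
        assert res_gi.log_likelihood >= res_single.log_likelihood - 0.1
        assert res_gi.log_likelihood - res_single.log_likelihood < 2.0

    def test_unknown_tier_rejected(self, tree8, small_pattern):
        with pytest.raises(ModelError):
            pc.fit_model(tree8, small_pattern, tier="bogus")


class TestPosteriorRates:
    def test_single_category_returns_global_rates(self, tree8, unit_mix,
                                                  small_pattern):
        res = pc.corrected_log_likelihood(tree8, small_pattern, unit_mix)
        rates = pc.posterior_rate_per_site(res, unit_mix)
        assert np.allclose(rates[:, 0], unit_mix.gains[0])
        assert np.allclose(rates[:, 1], unit_mix.losses[0])

    def test_variable_site_rated_above_constant_site(self, tree8):
        mix = pc.build_rate_mixture(pc.GainLossParams(
            model_tier="gamma_invariant", alpha=0.5, p_inv=0.1, K=4))
        # one maximally flipping column vs one constant column
        flip = [i % 2 for i in range(8)]
        pat = pc.PhyleticPattern(taxa=list(tree8.leaf_labels),
                                 characters=["flippy", "constant"],
                                 matrix=np.array([flip, [1] * 8]).T)
        res = pc.corrected_log_likelihood(tree8, pat, mix)
        rates = pc.posterior_rate_per_site(res, mix)
        assert rates[0].sum() >= rates[1].sum()
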