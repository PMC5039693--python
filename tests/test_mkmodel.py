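import math

import numpy as np
import pytest

from oracles import brute_likelihood, brute_marginal, build_random_tree, random_tips
from tmetrace.mkmodel import (
    RateMatrix2,
    RootPrior,
    compare_aic,
    fit,
    loglik,
    marginal_ancestral,
    transition_matrix,
)
from tmetrace.treeio import read_newick


class TestTransitionMatrix:
    def test_identity_at_zero_time(self):
        assert np.allclose(transition_matrix(RateMatrix2(0.3, 0.7), 0.0), np.eye(2))

    def test_identity_at_zero_rates(self):
        assert np.allclose(transition_matrix(RateMatrix2(0.0, 0.0), 5.0), np.eye(2))

    def test_er_closed_form(self):
        # q01 = q10 = 0.5, t = ln 2: P(stay) = (1 + e^{-2*0.5*ln2})/2 = 0.75
        P = transition_matrix(RateMatrix2(0.5, 0.5), math.log(2))
        assert P[0, 0] == pytest.approx(0.75, abs=1e-12)
        assert P[1, 1] == pytest.approx(0.75, abs=1e-12)

    def test_stationary_limit(self):
        P = transition_matrix(RateMatrix2(0.5, 0.5), 1e4)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_negative_time_raises(self):
        with pytest.raises(ValueError, match="negative"):
            transition_matrix(RateMatrix2(0.5, 0.5), -1.0)

    @pytest.mark.parametrize("q01,q10", [(0.2, 0.9), (0.0, 0.4), (1.3, 1.3)])
    def test_rows_sum_to_one_and_chapman_kolmogorov(self, q01, q10):
        q = RateMatrix2(q01, q10)
        for t1, t2 in [(0.1, 0.5), (1.0, 2.0), (0.0, 3.0)]:
            P1, P2, P12 = (transition_matrix(q, t) for t in (t1, t2, t1 + t2))
            assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(P1 @ P2, P12, atol=1e-10)


class TestLoglik:
    def test_two_tip_closed_form(self):
        tree = read_newick("(A:0.4,B:1.1);")
        q = RateMatrix2(0.5, 0.5)
        expected = math.log(
            sum(
                0.5
                * transition_matrix(q, 0.4)[r, 0]
                * transition_matrix(q, 1.1)[r, 0]
                for r in (0, 1)
            )
        )
        got = loglik(tree, {"A": 0, "B": 0}, q, RootPrior("flat"))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_er_flat_prior_complement_symmetry(self, rng):
        tree = build_random_tree(rng, 6)
        tips = random_tips(rng, tree, p_unknown=0.0)
        comp = {k: 1 - v for k, v in tips.items()}
        q = RateMatrix2(0.4, 0.4)
        assert loglik(tree, tips, q, RootPrior("flat")) == pytest.approx(
            loglik(tree, comp, q, RootPrior("flat")), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = build_random_tree(rng, int(rng.integers(2, 6)))
        tips = random_tips(rng, tree)
        q = RateMatrix2(float(rng.uniform(0.05, 2.0)), float(rng.uniform(0.05, 2.0)))
        prior = RootPrior(["flat", "stationary"][seed % 2])
        expected = math.log(brute_likelihood(tree, tips, q, prior))
        assert loglik(tree, tips, q, prior) == pytest.approx(expected, abs=1e-10)

    def test_missing_branch_length_raises(self):
        tree = read_newick("((A,B),C);")
        with pytest.raises(Exception, match="branch lengths required"):
            loglik(tree, {"A": 0, "B": 1, "C": 0}, RateMatrix2(1, 1), RootPrior("flat"))

    def test_impossible_data_is_minus_inf(self):
        tree = read_newick("(A:1,B:1);")
        # Dollo from a root fixed at absent cannot produce a present tip
        ll = loglik(tree, {"A": 1, "B": 0}, RateMatrix2(0.0, 0.5), RootPrior("fixed", 0))
        assert ll == -math.inf


class TestMarginalAncestral:
    def test_symmetric_two_tip_root_half(self):
        tree = read_newick("(A:1,B:1);")
        post = marginal_ancestral(tree, {"A": 0, "B": 1}, RateMatrix2(0.5, 0.5), RootPrior("flat"))
        assert post[tree.root] == pytest.approx(0.5, abs=1e-12)

    def test_known_leaves_deterministic(self, balanced4):
        post = marginal_ancestral(
            balanced4, {"A": 1, "B": 1, "C": 0, "D": 0}, RateMatrix2(0.3, 0.3), RootPrior("flat")
        )
        for leaf in balanced4.leaves():
            expected = 1.0 if leaf.label in "AB" else 0.0
            assert post[leaf.id] == pytest.approx(expected, abs=1e-12)

    def test_all_present_biases_all_nodes_present(self, balanced4):
        post = marginal_ancestral(
            balanced4, {l: 1 for l in "ABCD"}, RateMatrix2(0.4, 0.4), RootPrior("flat")
        )
        assert all(p > 0.5 for p in post.values())

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed + 500)
        tree = build_random_tree(rng, int(rng.integers(2, 6)))
        tips = random_tips(rng, tree)
        q = RateMatrix2(float(rng.uniform(0.05, 2.0)), float(rng.uniform(0.05, 2.0)))
        prior = RootPrior("flat")
        expected = brute_marginal(tree, tips, q, prior)
        got = marginal_ancestral(tree, tips, q, prior)
        for nid in tree.nodes:
            assert got[nid] == pytest.approx(expected[nid], abs=1e-10)


class TestFit:
    def test_constant_character_boundary_flagged(self, balanced4):
        res = fit(balanced4, {l: 1 for l in "ABCD"}, model="ER")
        assert res.boundary
        assert res.rates.q01 < 1e-6

    def test_er_nested_in_ard(self, rng):
        tree = build_random_tree(rng, 8)
        tips = random_tips(rng, tree, p_unknown=0.0)
        er = fit(tree, tips, model="ER")
        ard = fit(tree, tips, model="ARD")
        assert ard.loglik >= er.loglik - 1e-6
        assert er.aic == pytest.approx(2 * 1 - 2 * er.loglik)
        assert ard.aic == pytest.approx(2 * 2 - 2 * ard.loglik)

    def test_dollo_fit_has_zero_gain_rate(self, rng):
        from tmetrace.synthetic_data import simulate_mk, yule_tree

        tree = yule_tree(40, seed=11)
        rec = simulate_mk(tree, RateMatrix2(0.0, 0.4 / tree.height()), root_state=1, seed=4)
        res = fit(tree, rec.tips, model="dollo", prior=RootPrior("fixed", 1))
        assert res.rates.q01 == 0.0
        assert res.rates.q10 > 0


class TestCompareAic:
    def _fr(self, model, ll, k):
        from tmetrace.mkmodel import FitResult

        return FitResult(RateMatrix2(0.1, 0.1), ll, k, model=model)

    def test_delta_aic(self):
        ranking = compare_aic([self._fr("ER", -4.0, 1), self._fr("ARD", -4.25, 2)])
        assert [r["model"] for r in ranking] == ["ER", "ARD"]
        assert ranking[0]["delta_aic"] == 0.0
        assert ranking[1]["delta_aic"] == pytest.approx(2.5)

    def test_tie_prefers_fewer_parameters(self):
        # equal log-likelihood: AIC(ER) = 2 - 2ll < AIC(ARD) = 4 - 2ll
        ranking = compare_aic([self._fr("ARD", -3.0, 2), self._fr("ER", -3.0, 1)])
        assert ranking[0]["model"] == "ER"

    def test_single_fit(self):
        ranking = compare_aic([self._fr("ER", -1.0, 1)])
        assert ranking[0]["delta_aic"] == 0.0
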