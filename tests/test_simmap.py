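import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from oracles import brute_likelihood
from tmetrace.mkmodel import RateMatrix2, RootPrior, transition_matrix
from tmetrace.simmap import (
    CharacterHistory,
    ImpossibleDataError,
    ScenarioConfig,
    run_scenario,
    sample_history,
    sample_node_states,
    summarize,
)
from tmetrace.synthetic_data import simulate_mk, yule_tree
from tmetrace.treeio import read_newick


class TestSampleHistory:
    def test_leaf_states_match_data(self, balanced4, rng):
        tips = {"A": 1, "B": 0, "C": 0, "D": 1}
        for _ in range(20):
            h = sample_history(balanced4, tips, RateMatrix2(0.6, 0.6), RootPrior("flat"), rng)
            for leaf in balanced4.leaves():
                assert h.node_states[leaf.id] == tips[leaf.label]

    def test_history_invariants(self, balanced4, rng):
        tips = {"A": 1, "B": 0, "C": 0, "D": 1}
        for _ in range(50):
            h = sample_history(balanced4, tips, RateMatrix2(0.8, 0.4), RootPrior("flat"), rng)
            for node in balanced4.preorder():
                for cid in node.children:
                    bl = balanced4.nodes[cid].branch_length
                    s = h.node_states[node.id]
                    for t, new in h.events[cid]:
                        assert 0.0 < t < bl
                        assert new != s  # consecutive events change state
                        s = new
                    assert s == h.node_states[cid]  # path ends at child state

    def test_dollo_histories_contain_no_gains(self, rng):
        tree = yule_tree(20, seed=2)
        rec = simulate_mk(tree, RateMatrix2(0.0, 0.5 / tree.height()), root_state=1, seed=3)
        q = RateMatrix2(0.0, 0.5 / tree.height())
        for _ in range(20):
            h = sample_history(tree, rec.tips, q, RootPrior("fixed", 1), rng)
            assert h.counts()[0] == 0

    def test_impossible_data_raises(self):
        tree = read_newick("(A:1,B:1);")
        rng = np.random.default_rng(0)
        with pytest.raises(ImpossibleDataError):
            sample_history(tree, {"A": 1, "B": 0}, RateMatrix2(0.0, 0.5), RootPrior("fixed", 0), rng)

    def test_joint_node_states_match_enumeration(self):
        """Sampled ancestral states follow their exact conditional joint
        distribution (chi-square goodness of fit on a 3-tip tree)."""
        tree = read_newick("((A:0.7,B:1.2):0.6,C:0.9);")
        tips = {"A": 1, "B": 0, "C": 0}
        q = RateMatrix2(0.7, 0.4)
        prior = RootPrior("flat")
        P = {
            n.id: transition_matrix(q, n.branch_length)
            for n in tree.nodes.values()
            if n.parent is not None
        }
        internal = [n.id for n in tree.nodes.values() if not n.is_leaf]
        leaf_state = {n.id: tips[n.label] for n in tree.leaves()}

        # exact joint distribution of internal states given the data
        weights = {}
        for combo in itertools.product((0, 1), repeat=len(internal)):
            assign = dict(zip(internal, combo))
            assign.update(leaf_state)
            w = prior.vector(q)[assign[tree.root]]
            for n in tree.nodes.values():
                if n.parent is not None:
                    w *= P[n.id][assign[n.parent], assign[n.id]]
            weights[combo] = w
        total = sum(weights.values())
        expected_p = {k: v / total for k, v in weights.items()}

        rng = np.random.default_rng(123)
        order, states = sample_node_states(tree, tips, q, prior, rng, n=100_000)
        pos = {nid: i for i, nid in enumerate(order)}
        rows = np.stack([states[pos[nid]] for nid in internal])
        observed = {
            combo: int(np.sum(np.all(rows == np.array(combo)[:, None], axis=0)))
            for combo in expected_p
        }
        n = sum(observed.values())
        stat, pval = chisquare(
            [observed[c] for c in expected_p], [expected_p[c] * n for c in expected_p]
        )
        assert pval > 1e-4

    def test_single_branch_event_count_matches_discretized_chain(self):
        """Uniformization on one branch, both ends absent, vs a fine-grained
        discrete-time chain oracle for the number-of-changes distribution."""
        t, q = 1.5, RateMatrix2(0.8, 0.8)
        # oracle: discretized chain with step dt, conditioned on ending at 0
        n_steps = 2_000
        dt = t / n_steps
        p_flip = q.q01 * dt
        orng = np.random.default_rng(7)
        n_oracle = 40_000
        steps = orng.random((n_oracle, n_steps)) < p_flip
        ok = steps.sum(axis=1) % 2 == 0  # even number of flips ends at 0
        oracle_counts = steps[ok].sum(axis=1)

        rng = np.random.default_rng(8)
        from tmetrace.simmap import _uniformization_path

        samples = np.array(
            [len(_uniformization_path(q, t, 0, 0, rng)) for _ in range(30_000)]
        )
        mo, ms = oracle_counts.mean(), samples.mean()
        se = math.sqrt(oracle_counts.var() / len(oracle_counts) + samples.var() / len(samples))
        assert abs(mo - ms) < 3 * se + 3 * (q.q01 * dt) * (q.q01 * t)  # + discretization bias


class TestSummarize:
    def _map(self, states):
        return CharacterHistory(dict(states), {})

    def test_threshold_rule_counts_loss(self, balanced4):
        # parent (root) strongly present, one child strongly absent
        node_ids = list(balanced4.nodes)
        maps = []
        root = balanced4.root
        child = balanced4.nodes[root].children[0]
        for i in range(10):
            s = {nid: 1 for nid in node_ids}
            if i < 8:
                s[child] = 0
                for n in balanced4.subtree(child).nodes:
                    s[n] = 0
            maps.append(self._map(s))
        summary = summarize(balanced4, maps, threshold=0.5)
        assert summary.node_posterior[child] == pytest.approx(0.2)
        assert (child, "loss") in summary.threshold_changes

    def test_exact_half_support_is_uncalled(self, balanced4):
        """A node at exactly 50% support is not called for either state and
        its incident edges contribute no change (strict > rule)."""
        node_ids = list(balanced4.nodes)
        child = balanced4.nodes[balanced4.root].children[0]
        maps = []
        for i in range(10):
            s = {nid: 1 for nid in node_ids}
            if i % 2 == 0:
                s[child] = 0  # posterior exactly 0.5
            maps.append(self._map(s))
        summary = summarize(balanced4, maps, threshold=0.5)
        assert summary.node_posterior[child] == pytest.approx(0.5)
        assert summary.threshold_gains == 0
        assert summary.threshold_losses == 0

    def test_all_present_no_threshold_changes(self, balanced4):
        maps = [self._map({nid: 1 for nid in balanced4.nodes}) for _ in range(5)]
        summary = summarize(balanced4, maps)
        assert summary.threshold_gains == summary.threshold_losses == 0

    def test_mismatched_trees_raise(self, balanced4, chain3):
        m1 = self._map({nid: 1 for nid in balanced4.nodes})
        m2 = self._map({nid: 1 for nid in chain3.nodes})
        with pytest.raises(ValueError, match="different trees|match the given tree"):
            summarize(balanced4, [m1, m2])

    def test_mean_counts_from_events(self, balanced4):
        child = balanced4.nodes[balanced4.root].children[0]
        m1 = CharacterHistory({nid: 1 for nid in balanced4.nodes}, {child: [(0.5, 0), (0.8, 1)]})
        m2 = CharacterHistory({nid: 1 for nid in balanced4.nodes}, {})
        summary = summarize(balanced4, [m1, m2])
        assert summary.mean_gains == pytest.approx(0.5)
        assert summary.mean_losses == pytest.approx(0.5)


@pytest.fixture(scope="module")
def data():
    tree = yule_tree(30, seed=9)
    h = tree.height()
    rec = simulate_mk(tree, RateMatrix2(0.4 / h, 0.8 / h), root_state=1, seed=10)
    return tree, rec.tips


class TestRunScenario:
    def test_same_seed_bitwise_identical(self, data):
        tree, tips = data
        cfg = ScenarioConfig("er_unconstrained", n_sims=200, seed=42)
        s1 = run_scenario(tree, tips, cfg)
        s2 = run_scenario(tree, tips, cfg)
        assert s1.node_posterior == s2.node_posterior
        assert (s1.mean_gains, s1.mean_losses) == (s2.mean_gains, s2.mean_losses)
        assert (s1.threshold_gains, s1.threshold_losses) == (
            s2.threshold_gains,
            s2.threshold_losses,
        )

    def test_dollo_scenario_zero_gains(self, data):
        tree, tips = data
        s = run_scenario(tree, tips, ScenarioConfig("dollo", n_sims=500, seed=5))
        assert s.mean_gains == 0.0
        assert s.threshold_gains == 0

    def test_root_eared_scenario_root_posterior_one(self, data):
        tree, tips = data
        s = run_scenario(tree, tips, ScenarioConfig("er_root_eared", n_sims=200, seed=6))
        assert s.node_posterior[tree.root] == 1.0

    def test_dollo_losses_monotone_in_earless_tips(self):
        """Adding earless tips to a fixed tree never decreases the Dollo
        threshold loss count."""
        tree = yule_tree(24, seed=21)
        labels = tree.leaf_labels()
        prev = -1
        for n_earless in (4, 8, 12, 16):
            tips = {l: 1 for l in labels}
            tips.update({l: 0 for l in labels[:n_earless]})
            s = run_scenario(tree, tips, ScenarioConfig("dollo", n_sims=400, seed=3))
            assert s.threshold_losses >= prev
            prev = s.threshold_losses


class TestScenarioConfig:
    @pytest.mark.parametrize("kwargs", [{"n_sims": 0}, {"threshold": 0.0}, {"threshold": 1.0}])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig("dollo", **kwargs)
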