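"""Mk-model ancestral-state reconstruction vs brute-force enumeration."""

import itertools

import numpy as np
import pytest

from springwing.phylo import (
    MkModel,
    TraitPhylogeny,
    constrained_path_probability,
    fit_rates,
    marginal_ancestral_states,
    mk_log_likelihood,
    read_newick,
    read_traits,
    simulate_trait_evolution,
)
from springwing.phylo import _masks  # enumeration oracle needs the masks

FOUR_TIP = "((A:1.0,B:2.0)N1:1.5,(C:0.7,D:1.2)N2:0.8)R;"


def brute_force(ph, model, clamps=None):
    """Enumerate all internal-state assignments: joint likelihood and
    per-node marginals.  Independent oracle for the pruning algorithm."""
    n = len(ph.nodes)
    internals = [i for i in range(n) if not ph.is_tip[i]]
    masks = _masks(ph, clamps)
    P = {i: model.transition(ph.blen[i]) for i in range(n)}
    prior = model.prior()
    k = ph.n_states
    total = 0.0
    per_node = {i: np.zeros(k) for i in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        if any(masks[i][amap[i]] == 0 for i in internals):
            continue
        p = prior[amap[0]]
        for i in range(1, n):
            pa = amap[ph.parent[i]]
            if ph.is_tip[i]:
                p *= sum(P[i][pa, s] * masks[i][s] for s in range(k))
            else:
                p *= P[i][pa, amap[i]]
        total += p
        for i in internals:
            per_node[i][amap[i]] += p
    return total, {ph.node_ids[i]: per_node[i] / total for i in internals}


@pytest.fixture()
def four_tip():
    ph = read_newick(FOUR_TIP)
    ph.assign_traits({"A": "sync", "B": "sync", "C": "async", "D": "async"})
    return ph


class TestIO:
    def test_round_trip(self):
        ph = read_newick("(A:1.0,B:2.0)R;")
        again = read_newick(ph.write_newick())
        assert sorted(again.tip_labels) == ["A", "B"]
        assert again.total_branch_length == pytest.approx(3.0)

    def test_missing_tip_coded_ambiguous(self, four_tip):
        with pytest.warns(UserWarning, match="ambiguous"):
            report = four_tip.assign_traits({"A": "sync", "B": "async",
                                             "C": "sync"})
        assert report["missing_tips"] == ["D"]
        assert four_tip.tip_masks["D"].all()

    def test_unmatched_row_reported(self, four_tip):
        with pytest.warns(UserWarning):
            report = four_tip.assign_traits(
                {"A": "sync", "Zzz": "async"}
            )
        assert report["unmatched_rows"] == ["Zzz"]

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("((A:1.0,B:2.0;")

    def test_traits_csv_parsing(self):
        table = read_traits("species,state\nA,sync\nB,wingless\n")
        assert table == {"A": "sync", "B": "wingless"}

    def test_simulated_tree_bookkeeping(self):
        ph, truth = simulate_trait_evolution(50, MkModel(2, "ER", (0.5,)),
                                             seed=3, tree_depth=4.0)
        assert ph.n_tips == 50
        depth = max(leaf.distance_from_root()
                    for leaf in ph.tree.leaf_node_iter())
        assert depth == pytest.approx(4.0)
        assert len(truth) == len(ph.nodes)


class TestLikelihood:
    def test_single_branch_closed_form(self):
        """2-state equal rates on one branch: P_ij = (1 - e^(-2qt))/2."""
        q, t = 0.3, 1.7
        m = MkModel(2, "ER", (q,))
        P = m.transition(t)
        off = 0.5 * (1.0 - np.exp(-2.0 * q * t))
        assert P[0, 1] == pytest.approx(off, rel=1e-12)
        assert P[0, 0] == pytest.approx(1.0 - off, rel=1e-12)

    @pytest.mark.parametrize("newick,traits", [
        ("(A:1.0,B:0.5)R;", {"A": "sync", "B": "async"}),
        (FOUR_TIP, {"A": "sync", "B": "sync", "C": "async", "D": "async"}),
        (FOUR_TIP, {"A": "sync", "B": "unknown", "C": "async", "D": "wingless"}),
        ("(((A:0.4,B:0.4)N1:0.4,C:0.8)N2:0.4,(D:0.6,E:0.6)N3:0.6)R;",
         {"A": "sync", "B": "async", "C": "sync", "D": "async", "E": "sync"}),
    ])
    @pytest.mark.parametrize("model", [
        MkModel(2, "ER", (0.3,)),
        MkModel(2, "ARD", (0.45, 0.1)),
        MkModel(2, "ARD", (0.2, 0.9), root_prior="stationary"),
    ])
    def test_pruning_equals_enumeration(self, newick, traits, model):
        ph = read_newick(newick)
        ph.assign_traits(traits)
        ll = mk_log_likelihood(ph, model)
        total, _ = brute_force(ph, model)
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_zero_rate_consistency(self, four_tip):
        """q = 0: likelihood is positive only if a single state fits all."""
        m = MkModel(2, "ER", (0.0,))
        assert mk_log_likelihood(four_tip, m) == -np.inf
        ph = read_newick("(A:1.0,B:2.0)R;")
        ph.assign_traits({"A": "sync", "B": "sync"})
        # flat root prior: probability 1/2 the root was sync
        assert mk_log_likelihood(ph, m) == pytest.approx(np.log(0.5))

    def test_tip_order_invariance(self):
        m = MkModel(2, "ARD", (0.3, 0.7))
        ph1 = read_newick("((A:1.0,B:2.0)N1:1.5,C:0.5)R;")
        ph1.assign_traits({"A": "sync", "B": "async", "C": "sync"})
        ph2 = read_newick("((B:2.0,A:1.0)N1:1.5,C:0.5)R;")
        ph2.assign_traits({"A": "sync", "B": "async", "C": "sync"})
        assert mk_log_likelihood(ph1, m) == pytest.approx(
            mk_log_likelihood(ph2, m), abs=1e-12
        )


class TestMarginals:
    def test_symmetric_two_tip_root(self):
        ph = read_newick("(A:1.0,B:1.0)R;")
        ph.assign_traits({"A": "sync", "B": "async"})
        post = marginal_ancestral_states(ph, MkModel(2, "ER", (0.4,)))
        np.testing.assert_allclose(post["R"], [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("model", [
        MkModel(2, "ER", (0.3,)),
        MkModel(2, "ARD", (0.45, 0.1)),
        MkModel(2, "ARD", (0.2, 0.9), root_prior="stationary"),
    ])
    def test_marginals_equal_enumeration(self, four_tip, model):
        post = marginal_ancestral_states(four_tip, model)
        _, marg = brute_force(four_tip, model)
        for nid in post.node_ids:
            np.testing.assert_allclose(post[nid], marg[nid], atol=1e-10)

    def test_posteriors_normalized(self, four_tip):
        post = marginal_ancestral_states(four_tip, MkModel(2, "ARD", (0.5, 0.2)))
        np.testing.assert_allclose(post.probabilities.sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_low_rate_uniform_state(self):
        ph = read_newick(FOUR_TIP)
        ph.assign_traits({t: "sync" for t in "ABCD"})
        post = marginal_ancestral_states(ph, MkModel(2, "ER", (1e-8,)))
        assert post["R"][0] > 0.999999


class TestConstrainedPath:
    def test_single_node_path_is_plain_marginal(self, four_tip):
        m = MkModel(2, "ER", (0.3,))
        prod, factors = constrained_path_probability(four_tip, m, ["R"],
                                                     "synchronous")
        post = marginal_ancestral_states(four_tip, m)
        assert prod == pytest.approx(post["R"][0], abs=1e-12)
        assert factors == [prod]

    def test_chain_rule_equals_joint_enumeration(self, four_tip):
        """Product of clamped conditionals = joint P(all nodes sync)."""
        m = MkModel(2, "ARD", (0.45, 0.15))
        prod, _ = constrained_path_probability(four_tip, m, ["R", "N1"],
                                               "synchronous")
        total, _ = brute_force(four_tip, m)
        clamped, _ = brute_force(four_tip, m, clamps={"R": {0}, "N1": {0}})
        assert prod == pytest.approx(clamped / total, abs=1e-10)

    def test_clamping_certain_state_is_no_op(self):
        ph = read_newick(FOUR_TIP)
        ph.assign_traits({t: "sync" for t in "ABCD"})
        m = MkModel(2, "ER", (1e-6,))
        post0 = marginal_ancestral_states(ph, m)
        post1 = marginal_ancestral_states(ph, m, constraints={"R": {0}})
        np.testing.assert_allclose(post1["N1"], post0["N1"], atol=1e-6)

    def test_non_chain_path_rejected(self, four_tip):
        with pytest.raises(ValueError, match="ancestor"):
            constrained_path_probability(four_tip, MkModel(2, "ER", (0.3,)),
                                         ["N1", "N2"], "synchronous")


class TestRateFitting:
    def test_ard_nests_er(self):
        ph, _ = simulate_trait_evolution(100, MkModel(2, "ER", (0.4,)),
                                         seed=11, tree_depth=4.0)
        er = fit_rates(ph, "ER")
        ard = fit_rates(ph, "ARD")
        assert ard.log_likelihood >= er.log_likelihood - 1e-6
        assert er.aic == pytest.approx(2 - 2 * er.log_likelihood)

    def test_identical_tips_boundary_flagged(self):
        ph = read_newick(FOUR_TIP)
        ph.assign_traits({t: "sync" for t in "ABCD"})
        fit = fit_rates(ph, "ER")
        assert fit.boundary
        assert fit.rates[0] < 1e-6

    def test_rate_recovery_on_simulated_trees(self):
        """Median relative error of q over 50 seeded 200-tip trees < 25%."""
        q_true = 0.5
        errs = []
        for seed in range(50):
            ph, _ = simulate_trait_evolution(
                200, MkModel(2, "ER", (q_true,)), seed=seed, tree_depth=4.0
            )
            fit = fit_rates(ph, "ER")
            errs.append(abs(fit.rates[0] - q_true) / q_true)
        assert np.median(errs) < 0.25

    def test_too_few_informative_tips_rejected(self):
        ph = read_newick(FOUR_TIP)
        ph.assign_traits({"A": "sync", "B": "unknown", "C": "unknown",
                          "D": "unknown"})
        with pytest.raises(ValueError, match="unambiguous"):
            fit_rates(ph, "ER")


class TestSimulation:
    def test_zero_rate_inherits_root_state(self):
        ph, truth = simulate_trait_evolution(30, MkModel(2, "ER", (0.0,)),
                                             seed=5)
        states = {truth[nid] for nid in truth}
        assert len(states) == 1

    def test_high_rate_tips_near_stationary(self):
        """Large q x depth: tip states approach the 50/50 stationary mix."""
        fracs = []
        for seed in range(10):
            ph, truth = simulate_trait_evolution(
                100, MkModel(2, "ER", (20.0,)), seed=seed, tree_depth=5.0
            )
            tips = [truth[ph.node_ids[i]] for i in range(len(ph.nodes))
                    if ph.is_tip[i]]
            fracs.append(np.mean(tips))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.1)

    def test_seed_determinism(self):
        a, ta = simulate_trait_evolution(40, MkModel(2, "ER", (0.5,)), seed=9)
        b, tb = simulate_trait_evolution(40, MkModel(2, "ER", (0.5,)), seed=9)
        assert a.write_newick() == b.write_newick()
        assert ta == tb

    def test_reconstruction_calibration(self):
        """Nodes with posterior ~ p are correct ~ p of the time."""
        hits, probs = [], []
        for seed in range(20):
            ph, truth = simulate_trait_evolution(
                80, MkModel(2, "ER", (0.5,)), seed=100 + seed, tree_depth=3.0
            )
            fit = fit_rates(ph, "ER")
            post = marginal_ancestral_states(ph, fit)
            for nid in post.node_ids:
                p = post[nid]
                k = int(np.argmax(p))
                probs.append(p[k])
                hits.append(1.0 if truth[nid] == k else 0.0)
        probs, hits = np.asarray(probs), np.asarray(hits)
        # bin by confidence; observed accuracy within sampling error
        for lo, hi in ((0.5, 0.7), (0.7, 0.9), (0.9, 1.0)):
            m = (probs >= lo) & (probs < hi)
            if m.sum() < 30:
                continue
            expected = probs[m].mean()
            se = np.sqrt(expected * (1 - expected) / m.sum())
            assert abs(hits[m].mean() - expected) < 4 * se + 0.02
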