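import itertools

import numpy as np
import pytest

from tapirgeo import study
from tapirgeo.coalescent import simultaneous_split_tree
from tapirgeo.phylogeo import (
    fitch_changes,
    run_scenarios,
    slatkin_maddison_s,
    sm_hypothesis_test,
)
from tapirgeo.seq_io import InputError
from tapirgeo.trees import GeneTree, Node, read_newick

from oracles import all_rooted_binary_trees, brute_parsimony


def tree_of(newick):
    return read_newick(newick)


class TestSlatkinMaddisonS:
    def test_reciprocally_monophyletic_groups_attain_lower_bound(self):
        t = tree_of("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,((c1:1,c2:1):1,(d1:1,d2:1):1):1);")
        states = {f"{g}{i}": g for g in "abcd" for i in (1, 2)}
        assert slatkin_maddison_s(t, states) == 3  # K - 1

    def test_alternating_tips_need_many_changes(self):
        t = tree_of("(((a1:1,b1:1):1,(a2:1,b2:1):1):1,(a3:1,b3:1):1);")
        states = {l: l[0] for l in ["a1", "a2", "a3", "b1", "b2", "b3"]}
        assert slatkin_maddison_s(t, states) == 3

    def test_unlabeled_tip_rejected(self):
        t = tree_of("(a:1,b:1);")
        with pytest.raises(InputError, match="unlabeled"):
            slatkin_maddison_s(t, {"a": "x"})

    @pytest.mark.parametrize("n_tips,n_states", [(4, 2), (4, 3), (5, 2)])
    def test_fitch_equals_brute_force_exhaustive(self, n_tips, n_states):
        labels = [f"t{i}" for i in range(n_tips)]
        state_pool = "XYZ"[:n_states]
        count = 0
        for root in all_rooted_binary_trees(labels):
            tree = GeneTree(root)
            for combo in itertools.product(state_pool, repeat=n_tips):
                states = dict(zip(labels, combo))
                assert fitch_changes(tree, states) == brute_parsimony(tree, states)
                count += 1
        assert count > 0

    def test_fitch_equals_brute_force_sampled_six_tips(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(6)]
        trees = list(itertools.islice(all_rooted_binary_trees(labels), 40))
        for tree_root in trees:
            tree = GeneTree(tree_root)
            for _ in range(5):
                combo = rng.choice(list("XYZW"), size=6)
                states = dict(zip(labels, combo))
                assert fitch_changes(tree, states) == brute_parsimony(tree, states)

    def test_invariant_to_child_order_and_state_relabeling(self):
        t1 = tree_of("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = tree_of("(((d:1,c:1):1,(b:1,a:1):1));")
        states = {"a": "N", "b": "S", "c": "N", "d": "S"}
        swapped = {k: {"N": "S", "S": "N"}[v] for k, v in states.items()}
        assert slatkin_maddison_s(t1, states) == slatkin_maddison_s(t2, states)
        assert slatkin_maddison_s(t1, states) == slatkin_maddison_s(t1, swapped)

    def test_polytomy_resolution_reports_minimum(self):
        t = tree_of("(a:1,b:1,c:1,d:1);")
        states = {"a": "x", "b": "x", "c": "y", "d": "y"}
        assert slatkin_maddison_s(t, states, seed=0) == 1

    def test_bounds(self):
        # K-1 <= s <= n - max deme size, on deme-tagged simulated trees
        from tapirgeo.coalescent import simulate_gene_tree

        sizes = {"a": 4, "b": 3, "c": 2}
        pt = simultaneous_split_tree(sizes, 100.0, 1000.0)
        rng = np.random.default_rng(5)
        for _ in range(20):
            gt = simulate_gene_tree(pt, rng)
            states = {l.label: l.deme for l in gt.leaves()}
            s = slatkin_maddison_s(gt, states)
            assert 2 <= s <= sum(sizes.values()) - max(sizes.values())


class TestHypothesisTest:
    def test_monophyly_limit_null_concentrated_at_lower_bound(self):
        # tau >> Ne: demes reciprocally monophyletic, s = K-1 = 3 always
        pt = study.null_population_tree(500000, 100)
        res = sm_hypothesis_test(
            pt, study.region_identity_grouping(), reps=200, seed=1, s_observed=3
        )
        assert res.mean_s == pytest.approx(3.0)
        assert res.ci99 == (3, 3)
        assert res.p == pytest.approx(1.0, abs=0.01)

    def test_low_observed_s_rejected_under_shallow_null(self):
        pt = study.null_population_tree(1250, 10000)
        res = sm_hypothesis_test(
            pt, study.region_identity_grouping(), reps=300, seed=2, s_observed=4
        )
        assert res.p <= 0.01
        assert res.ci99[0] > 4

    def test_few_reps_warns(self):
        pt = study.null_population_tree(1000, 100)
        with pytest.warns(UserWarning, match="replicates"):
            sm_hypothesis_test(pt, study.region_identity_grouping(), reps=50, seed=0)

    def test_missing_state_rejected(self):
        pt = study.null_population_tree(1000, 100)
        with pytest.raises(InputError, match="missing"):
            sm_hypothesis_test(pt, {"North Amazon": "N"}, reps=100, seed=0)

    def test_stability_across_rep_doubling(self):
        pt = study.null_population_tree(1250, 10000)
        r1 = sm_hypothesis_test(pt, study.region_identity_grouping(), reps=400, seed=3)
        r2 = sm_hypothesis_test(pt, study.region_identity_grouping(), reps=800, seed=4)
        se = np.std(r1.null_s) / np.sqrt(len(r1.null_s))
        assert abs(r1.mean_s - r2.mean_s) < 2 * (2 * se)


class TestRunScenarios:
    def test_grid_shape_order_and_determinism(self):
        grid = [(1250, 1000), (1250, 5000), (5000, 1000), (5000, 5000)]
        out1 = run_scenarios(
            grid, study.null_population_tree, study.region_identity_grouping(),
            reps=100, seed=11, s_observed=4,
        )
        out2 = run_scenarios(
            grid, study.null_population_tree, study.region_identity_grouping(),
            reps=100, seed=11, s_observed=4,
        )
        assert len(out1) == 4
        assert [r.scenario["generations"] for r in out1] == [g for g, _ in grid]
        assert [r.null_s for r in out1] == [r.null_s for r in out2]

    def test_larger_ne_inflates_null_s_at_fixed_tau(self):
        # more incomplete lineage sorting -> stochastically larger s
        grid = [(1250, 10000), (1250, 1000000)]
        out = run_scenarios(
            grid, study.null_population_tree, study.region_identity_grouping(),
            reps=300, seed=21,
        )
        assert out[1].mean_s > out[0].mean_s
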