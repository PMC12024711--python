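import itertools
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splenopt.cohort import ARMS
from splenopt.errors import ConfigurationError, SchemaError
from splenopt.tree import (
    Node,
    PolicyTree,
    exhaustive_policy_tree,
    prescribe,
    train_policy_tree,
    tune,
)


def _random_problem(seed, n=200, f=3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{j}": np.round(rng.normal(size=n), 1) for j in range(f)})
    G = rng.normal(size=(n, 3))
    return G, X


class TestTrainPolicyTree:
    def test_dominant_arm_collapses_to_single_leaf(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        G = np.column_stack([np.full(100, 0.5), np.full(100, 0.1),
                             np.full(100, 0.9)])
        t = train_policy_tree(G, X, depth=3, min_leaf=5, cp=1e-3, seed=0)
        assert t.n_splits == 0
        assert t.root.treatment == "AE"

    def test_depth1_objective_matches_hand_enumeration(self):
        # 10 rows, one binary feature: candidates are {no split} x 3 arms and
        # {split at 0.5} x 3 x 3 arm pairs; enumerate them all directly
        rng = np.random.default_rng(42)
        x = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        G = rng.normal(size=(10, 3))
        best = min(G.sum(axis=0))  # no split
        for a0, a1 in itertools.product(range(3), range(3)):
            best = min(best, G[x == 0, a0].sum() + G[x == 1, a1].sum())
        t = train_policy_tree(G, pd.DataFrame({"x": x}), depth=1, min_leaf=1,
                              cp=0.0, seed=1, n_restarts=5)
        assert t.objective * 10 == pytest.approx(best, abs=1e-9)

    def test_min_leaf_respected_everywhere(self):
        G, X = _random_problem(3, n=300)
        t = train_policy_tree(G, X, depth=4, min_leaf=25, cp=0.0, seed=2)
        assert all(leaf.n_train >= 25 for _, leaf in t.leaves())

    def test_infeasible_depth_is_reduced_with_warning(self):
        G, X = _random_problem(4, n=50)
        t = train_policy_tree(G, X, depth=6, min_leaf=10, cp=0.0, seed=0)
        assert t.metadata["warnings"]
        assert t.depth <= 2  # 10 * 2^2 <= 50 < 10 * 2^3

    def test_objective_is_consistent_with_prescriptions(self):
        G, X = _random_problem(5, n=250)
        cp = 1e-3
        t = train_policy_tree(G, X, depth=3, min_leaf=10, cp=cp, seed=3)
        arm = t.prescribe(X).map({a: i for i, a in enumerate(ARMS)}).to_numpy()
        recomputed = G[np.arange(len(G)), arm].mean() + cp * t.n_splits
        assert t.objective == pytest.approx(recomputed, abs=1e-12)

    def test_fixed_seed_gives_identical_json(self):
        G, X = _random_problem(6, n=300)
        t1 = train_policy_tree(G, X, depth=3, min_leaf=10, cp=0.0, seed=7)
        t2 = train_policy_tree(G, X, depth=3, min_leaf=10, cp=0.0, seed=7)
        assert t1.to_json() == t2.to_json()

    def test_empty_input_rejected(self):
        with pytest.raises((ConfigurationError, SchemaError)):
            train_policy_tree(np.empty((0, 3)), pd.DataFrame({"x": []}),
                              depth=1, min_leaf=1)


class TestExhaustive:
    def test_depth0_prescribes_argmin_of_column_means(self):
        G, X = _random_problem(8)
        t = exhaustive_policy_tree(G, X, depth=0, min_leaf=1)
        assert t.root.treatment == ARMS[int(G.sum(axis=0).argmin())]
        assert t.objective == pytest.approx(G.sum(axis=0).min() / len(G))

    def test_exact_is_lower_bound_for_heuristic_depth1(self):
        for seed in range(5):
            G, X = _random_problem(100 + seed, n=200, f=3)
            ex = exhaustive_policy_tree(G, X, depth=1, min_leaf=5)
            ls = train_policy_tree(G, X, depth=1, min_leaf=5, cp=0.0, seed=seed)
            assert ex.objective <= ls.objective + 1e-12

    def test_guards_refuse_large_inputs(self):
        G, X = _random_problem(9, n=250)
        with pytest.raises(ConfigurationError):
            exhaustive_policy_tree(G, X, depth=3)
        big_G, big_X = _random_problem(10, n=2001)
        with pytest.raises(ConfigurationError):
            exhaustive_policy_tree(big_G, big_X, depth=2)


class TestPrescribe:
    def test_single_leaf_is_constant(self, toy_cohort):
        t = PolicyTree(root=Node(treatment="OBS"))
        assert (t.prescribe(toy_cohort) == "OBS").all()

    def test_figure_style_walkthrough(self, figure_style_tree):
        # hr=120, sbp=77 -> shock index 1.558 >= 1.551; pRBC yes -> splenectomy
        row = pd.DataFrame({"shock_index": [120 / 77], "prbc_1h": [1]})
        assert prescribe(figure_style_tree, row).iloc[0] == "SPLENECTOMY"
        no_prbc = pd.DataFrame({"shock_index": [120 / 77], "prbc_1h": [0]})
        assert prescribe(figure_style_tree, no_prbc).iloc[0] == "AE"

    def test_boundary_value_goes_right(self, figure_style_tree):
        row = pd.DataFrame({"shock_index": [1.551], "prbc_1h": [0]})
        # exactly at the threshold: >= goes right, i.e. down the pRBC branch
        assert figure_style_tree.leaf_ids(row).iloc[0] == 1

    def test_missing_value_follows_majority_branch(self, figure_style_tree):
        figure_style_tree.root.missing_goes_left = True
        row = pd.DataFrame({"shock_index": [np.nan], "prbc_1h": [1]})
        assert prescribe(figure_style_tree, row).iloc[0] == "AE"
        figure_style_tree.root.missing_goes_left = False
        assert prescribe(figure_style_tree, row).iloc[0] == "SPLENECTOMY"

    def test_unknown_feature_raises(self, figure_style_tree):
        with pytest.raises(SchemaError):
            figure_style_tree.prescribe(pd.DataFrame({"shock_index": [1.0]}))

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_json_round_trip_preserves_prescriptions(self, seed):
        G, X = _random_problem(seed, n=120, f=3)
        t = train_policy_tree(G, X, depth=2, min_leaf=5, cp=0.0, seed=seed,
                              n_restarts=2)
        back = PolicyTree.from_json(t.to_json())
        rng = np.random.default_rng(seed + 1)
        fresh = pd.DataFrame(
            {c: rng.normal(size=60) for c in X.columns})
        assert (back.prescribe(fresh) == t.prescribe(fresh)).all()


class TestTune:
    def test_degenerate_rewards_tie_break_to_smallest_depth_then_cp(self):
        rng = np.random.default_rng(1)
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        G = np.column_stack([np.full(n, 0.9), np.full(n, 0.1), np.full(n, 0.9)])
        winner, table = tune(G[:100], X.head(100), G[100:], X.tail(100),
                             depth_grid=(3, 4), cp_grid=(0.0, 1e-3),
                             min_leaf=10, seed=0, n_restarts=1)
        assert table.val_value.nunique() == 1  # all cells tie
        assert winner.metadata["tuned_depth"] == 3
        assert winner.metadata["tuned_cp"] == 0.0

    def test_grid_table_has_one_row_per_cell(self):
        G, X = _random_problem(12, n=240)
        _, table = tune(G[:120], X.head(120), G[120:], X.tail(120),
                        depth_grid=(3, 4, 5), cp_grid=(0.0, 1e-2),
                        min_leaf=10, seed=0, n_restarts=1)
        assert len(table) == 3 * 2

    def test_empty_grid_rejected(self):
        G, X = _random_problem(13)
        with pytest.raises(ConfigurationError):
            tune(G[:100], X.head(100), G[100:], X.tail(100), depth_grid=(),
                 cp_grid=(0.0,))

    def test_dot_export_mentions_every_leaf(self):
        G, X = _random_problem(14, n=200)
        t = train_policy_tree(G, X, depth=2, min_leaf=20, cp=0.0, seed=0)
        dot = t.to_dot(title="demo")
        assert dot.startswith("digraph")
        assert dot.count("Prescribe") == t.n_leaves
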