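import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybtherm import rank_guide as rg
from hybtherm.errors import InputError, NumericalDomainError, StateError


def _table(rng, n=2000, noise=1.0, step_at=0.5, jump=10.0, n_noise_vars=1):
    x1 = rng.uniform(0, 1, n)
    cols = {"x1": x1}
    for k in range(n_noise_vars):
        cols[f"z{k}"] = rng.normal(size=n)
    y = jump * (x1 > step_at) + noise * rng.normal(size=n)
    return rg.FeatureTable(X=pd.DataFrame(cols), y=y)


class TestFitTree:
    def test_constant_response_gives_flagged_root(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        data = rg.FeatureTable(X=X, y=np.full(200, 3.0))
        tree = rg.fit_tree(data, rg.TreeConfig(prune=False))
        assert tree.constant_response
        assert tree.root.is_leaf
        assert (rg.importance(tree).table["mean"] == 0.0).all()

    def test_step_function_recovered(self):
        rng = np.random.default_rng(42)
        data = _table(rng, n=2000)
        tree = rg.fit_tree(data, rg.TreeConfig(prune=False, max_depth=4))
        root = tree.root
        assert tree.feature_names[root.split_var] == "x1"
        x1 = np.sort(data.X["x1"].to_numpy())
        spacing = np.diff(x1).max()
        assert abs(root.threshold - 0.5) <= max(0.02, 5 * spacing)

    def test_single_predictor_always_wins(self, rng):
        X = pd.DataFrame({"only": rng.uniform(0, 1, 500)})
        y = np.sin(6 * X["only"].to_numpy()) + 0.1 * rng.normal(size=500)
        tree = rg.fit_tree(rg.FeatureTable(X=X, y=y), rg.TreeConfig(prune=False))
        splits = tree.split_nodes()
        assert splits and all(s.split_var == 0 for s in splits)

    def test_min_rows_enforced(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(InputError):
            rg.fit_tree(rg.FeatureTable(X=X, y=rng.normal(size=10)))

    def test_children_partition_parent(self):
        rng = np.random.default_rng(1)
        data = _table(rng, n=800)
        tree = rg.fit_tree(data, rg.TreeConfig(prune=False))
        for node in tree.split_nodes():
            assert node.left.size + node.right.size == node.size


class TestPruning:
    def test_one_se_rule_holds_on_trace(self):
        rng = np.random.default_rng(7)
        data = _table(rng, n=800, noise=2.0)
        tree = rg.fit_tree(data, rg.TreeConfig(cv_folds=5, max_depth=6))
        trace = tree.pruning_trace
        assert trace is not None
        assert trace["final_error"] <= trace["one_se_threshold"] + 1e-9

    def test_pruned_tree_not_larger(self):
        rng = np.random.default_rng(7)
        data = _table(rng, n=800, noise=2.0)
        cfg = rg.TreeConfig(cv_folds=5, max_depth=6)
        pruned = rg.fit_tree(data, cfg)
        grown = rg.fit_tree(data, rg.TreeConfig(cv_folds=5, max_depth=6, prune=False))
        assert pruned.n_leaves() <= grown.n_leaves()

    def test_ranking_stable_under_pruning(self):
        rng = np.random.default_rng(3)
        data = _table(rng, n=1500, noise=1.0, n_noise_vars=2)
        top_pruned = rg.importance(rg.fit_tree(data, rg.TreeConfig(cv_folds=5))).ranking[0]
        top_grown = rg.importance(rg.fit_tree(data, rg.TreeConfig(prune=False))).ranking[0]
        assert top_pruned == top_grown == "x1"


class TestImportance:
    def test_unfitted_tree_rejected(self):
        tree = rg.RegressionTree(["a"], rg.TreeConfig())
        with pytest.raises(StateError):
            rg.importance(tree)

    def test_single_split_score_is_chi2_times_sqrt_n(self):
        rng = np.random.default_rng(5)
        data = _table(rng, n=600)
        tree = rg.fit_tree(data, rg.TreeConfig(prune=False, max_depth=1))
        splits = tree.split_nodes()
        assert len(splits) == 1
        node = splits[0]
        imp = rg.importance(tree)
        expected = node.chi2 * math.sqrt(node.size)
        assert imp.table.loc[tree.feature_names[node.split_var], "mean"] == pytest.approx(expected)

    def test_multi_split_score_is_hand_summed(self):
        rng = np.random.default_rng(6)
        data = _table(rng, n=1200, n_noise_vars=2)
        tree = rg.fit_tree(data, rg.TreeConfig(prune=False, max_depth=3))
        imp = rg.importance(tree)
        hand = np.zeros(len(tree.feature_names))
        for node in tree.split_nodes():
            hand[node.split_var] += node.chi2 * math.sqrt(node.size)
        np.testing.assert_allclose(imp.table["mean"].to_numpy(), hand)
        assert imp.table["relative"].max() == 1.0

    def test_losing_variables_switch(self):
        rng = np.random.default_rng(8)
        data = _table(rng, n=800, n_noise_vars=2)
        cfg = rg.TreeConfig(prune=False, max_depth=2, losing_vars_score=True)
        tree = rg.fit_tree(data, cfg)
        imp = rg.importance(tree)
        # under the switch every tested variable can accrue score
        assert (imp.table["mean"] > 0).sum() >= 2


class TestBootstrap:
    def test_seed_determinism_bit_for_bit(self, rng):
        data = _table(np.random.default_rng(9), n=400)
        a = rg.bootstrap_importance(data, ("subsample", 0.9), n_rep=10, seed=123)
        b = rg.bootstrap_importance(data, ("subsample", 0.9), n_rep=10, seed=123)
        assert a.table.equals(b.table)
        np.testing.assert_array_equal(a.reps, b.reps)

    def test_constant_data_has_zero_sd(self):
        X = pd.DataFrame({"a": np.tile([1.0, 2.0], 100), "b": np.tile([3.0, 4.0], 100)})
        data = rg.FeatureTable(X=X, y=np.full(200, 5.0))
        imp = rg.bootstrap_importance(data, ("resample", 200), n_rep=5, seed=0)
        assert (imp.table["sd"] == 0.0).all()

    def test_protocols_and_validation(self):
        data = _table(np.random.default_rng(10), n=300)
        with pytest.raises(InputError):
            rg.bootstrap_importance(data, ("subsample", 0.9), n_rep=1)
        with pytest.raises(InputError):
            rg.bootstrap_importance(data, ("noise", 0.9), n_rep=5)
        imp = rg.bootstrap_importance(data, "resample:300", n_rep=5, seed=1)
        assert imp.table.loc["x1", "relative"] == 1.0

    def test_permuting_informative_column_destroys_its_importance(self):
        rng = np.random.default_rng(11)
        n = 1500
        x1 = rng.uniform(0, 1, n)
        x2 = rng.uniform(0, 1, n)
        y = 8.0 * (x1 > 0.5) + 4.0 * x2 + rng.normal(size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        data = rg.FeatureTable(X=X, y=y)
        intact = rg.bootstrap_importance(data, ("subsample", 0.9), n_rep=20, seed=2)
        X_perm = X.copy()
        X_perm["x1"] = rng.permutation(X_perm["x1"].to_numpy())
        broken = rg.bootstrap_importance(
            rg.FeatureTable(X=X_perm, y=y), ("subsample", 0.9), n_rep=20, seed=2
        )
        assert intact.table.loc["x1", "mean"] > 0
        assert broken.table.loc["x1", "mean"] < broken.table.loc["x2", "mean"]
        assert broken.table.loc["x1", "mean"] < 0.2 * intact.table.loc["x1", "mean"]


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        rho, _ = rg.spearman(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = rg.spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_exact_permutation_brute_force(self, rng):
        for n in (5, 6, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = rg.spearman(x, y)
            # independent recomputation of rho and its permutation tail
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rho_ref = float(np.corrcoef(rx, ry)[0, 1])
            count = sum(
                1
                for perm in itertools.permutations(range(n))
                if abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(rho_ref) - 1e-12
            )
            assert rho == pytest.approx(rho_ref, abs=1e-12)
            assert p == pytest.approx(count / math.factorial(n), abs=1e-12)

    def test_large_sample_uses_t_approximation(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, p = rg.spearman(x, y)
        rho_ref, p_ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(float(rho_ref))
        assert p == pytest.approx(float(p_ref))

    def test_errors(self):
        with pytest.raises(NumericalDomainError):
            rg.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(InputError):
            rg.spearman([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InputError):
            rg.spearman([1.0, 2.0, 3.0], [1.0, 2.0])
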