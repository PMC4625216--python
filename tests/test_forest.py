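"""forest_classify: Gini machinery, forest, ROC/AUC, permutation, protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from subshape.forest import (
    ClassifierEvaluation,
    FeatureMatrix,
    RandomForestModel,
    best_split,
    evaluate_feature_subsets,
    evaluate_protocol,
    gini,
    grow_tree,
    importance_to_surfaces,
    permutation_pvalue,
    roc_auc,
)


def brute_force_split(X, y):
    """Exhaustive enumeration over all features and midpoint thresholds."""
    n = len(y)
    g0 = gini(np.bincount(y, minlength=2))

    def child_gini(labels):
        # same arithmetic as the implementation: 1 - sum of squared shares
        c = np.bincount(labels, minlength=2).astype(float)
        p = c / c.sum()
        return 1.0 - float(np.sum(p * p))

    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            left = X[:, f] <= thr
            nl = int(left.sum())
            gain = (g0 - (nl / n) * child_gini(y[left])
                    - ((n - nl) / n) * child_gini(y[~left]))
            key = (gain, -f, -thr)
            if best is None or key > best[0]:
                best = (key, (f, thr, gain))
    return None if best is None else best[1]


class TestGini:
    def test_worked_values(self):
        assert gini([10, 0]) == 0.0
        assert gini([5, 5]) == 0.5
        assert gini([3, 1]) == 0.375

    def test_empty_node_error(self):
        with pytest.raises(ValueError):
            gini([0, 0])

    def test_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.integers(0, 20, size=2)
            if c.sum() == 0:
                continue
            assert 0.0 <= gini(c) <= 0.5


class TestBestSplit:
    def test_worked_example(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        f, thr, gain = best_split(X, y, [0])
        assert (f, thr, gain) == (0, 2.5, 0.5)

    def test_pure_node_error(self):
        with pytest.raises(ValueError, match="pure"):
            best_split(np.ones((3, 1)), np.zeros(3, int), [0])

    def test_constant_features_no_split(self):
        X = np.ones((4, 2))
        assert best_split(X, np.array([0, 1, 0, 1]), [0, 1]) is None

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        X = np.round(rng.normal(size=(n, 2)), 2)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        got = best_split(X, y, [0, 1])
        want = brute_force_split(X, y)
        if want is None or want[2] <= 0 and got is None:
            return
        assert got is not None
        gf, gt, gg = got
        wf, wt, wg = want
        assert np.isclose(gg, wg, atol=1e-12)
        assert (gf, gt) == (wf, wt) or np.isclose(gt, wt)

    def test_tie_breaks_lower_feature_then_threshold(self):
        # identical columns: both give the same gain; feature 0 must win
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        f, thr, _ = best_split(X, y, [1, 0])
        assert f == 0 and thr == 2.5


class TestGrowTree:
    def test_separable_depth_one(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        t = grow_tree(X, y, mtry=1, rng=np.random.default_rng(0))
        assert not t.is_leaf and t.left.is_leaf and t.right.is_leaf
        assert t.left.leaf_class == 0 and t.right.leaf_class == 1

    def test_identical_rows_majority_leaf(self):
        X = np.ones((5, 2))
        y = np.array([0, 1, 1, 0, 0])
        t = grow_tree(X, y, mtry=2, rng=np.random.default_rng(0))
        assert t.is_leaf and t.leaf_class == 0

    def test_leaf_tie_to_lower_class(self):
        t = grow_tree(np.ones((4, 1)), np.array([0, 1, 0, 1]), mtry=1,
                      rng=np.random.default_rng(0))
        assert t.is_leaf and t.leaf_class == 0

    def test_conservation_at_every_node(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, 40)
        t = grow_tree(X, y, mtry=2, rng=rng)

        def check(node):
            if node.is_leaf:
                return
            assert np.array_equal(node.counts, node.left.counts + node.right.counts)
            assert node.gain >= 0
            check(node.left)
            check(node.right)

        check(t)

    def test_deterministic_given_rng(self):
        rng_a, rng_b = np.random.default_rng(5), np.random.default_rng(5)
        X = np.random.default_rng(1).normal(size=(30, 4))
        y = np.random.default_rng(2).integers(0, 2, 30)
        ta = grow_tree(X, y, 2, rng_a)
        tb = grow_tree(X, y, 2, rng_b)

        def flat(n):
            return ([] if n.is_leaf else [(n.feature, n.threshold)]
                    + flat(n.left) + flat(n.right))

        assert flat(ta) == flat(tb)


def _two_gaussians(n=60, p=10, d=2.5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += d * y
    tags = tuple(("s1", "RD", i) for i in range(p))
    return FeatureMatrix(X, y, tags)


class TestForestModel:
    def test_seeded_determinism(self):
        fm = _two_gaussians()
        a = RandomForestModel(fm, n_trees=20, seed=3).fit()
        b = RandomForestModel(fm, n_trees=20, seed=3).fit()
        assert np.array_equal(a.predict_scores(fm.X), b.predict_scores(fm.X))
        assert np.allclose(a.importance()["importance"],
                           b.importance()["importance"])

    def test_single_class_error(self):
        fm = _two_gaussians()
        with pytest.raises(ValueError, match="class"):
            # rejected either at matrix construction or at fit time
            bad = FeatureMatrix(fm.X, np.zeros_like(fm.y), fm.tags)
            RandomForestModel(bad, n_trees=5).fit()

    def test_training_accuracy_on_separated_data(self):
        fm = _two_gaussians(d=4.0, seed=1)
        res = RandomForestModel(fm, n_trees=50, seed=0).fit()
        acc = (res.predict(fm.X) == fm.y).mean()
        assert acc > 0.95

    def test_bootstrap_unique_fraction(self):
        fm = _two_gaussians(n=100, seed=2)
        res = RandomForestModel(fm, n_trees=50, seed=0).fit()
        fr = np.mean([len(np.unique(b)) / 100 for b in res.bootstrap_indices])
        assert abs(fr - 0.634) < 0.05

    def test_default_mtry(self):
        fm = _two_gaussians(p=100)
        assert RandomForestModel(fm).mtry == 10

    def test_scores_in_unit_interval_and_single_tree_binary(self):
        fm = _two_gaussians(seed=4)
        res1 = RandomForestModel(fm, n_trees=1, seed=0).fit()
        s1 = res1.predict_scores(fm.X)
        assert set(np.unique(s1)) <= {0.0, 1.0}
        res = RandomForestModel(fm, n_trees=30, seed=0).fit()
        s = res.predict_scores(fm.X)
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_feature_mismatch_error(self):
        fm = _two_gaussians()
        res = RandomForestModel(fm, n_trees=5, seed=0).fit()
        with pytest.raises(ValueError):
            res.predict_scores(fm.X[:, :4])
        other = FeatureMatrix(fm.X, fm.y, tuple(("s2", "RD", i)
                                                for i in range(fm.X.shape[1])))
        with pytest.raises(ValueError, match="tags"):
            res.predict_scores(other)


class TestImportance:
    def test_unused_feature_zero(self):
        fm = _two_gaussians(d=5.0, seed=5)
        res = RandomForestModel(fm, n_trees=20, seed=0).fit()
        imp = res.importance()
        used = set()
        for t in res.trees:
            stack = [t]
            while stack:
                n = stack.pop()
                if not n.is_leaf:
                    used.add(n.feature)
                    stack += [n.left, n.right]
        unused = [i for i in range(fm.X.shape[1]) if i not in used]
        assert all(imp["importance"][i] == 0 for i in unused)
        assert all(imp["importance"][i] > 0 for i in used)

    def test_single_tree_direct_eq5(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        fm = FeatureMatrix(X, y, (("s1", "RD", 3),))
        res = RandomForestModel(fm, n_trees=1, mtry=1, seed=0).fit()
        imp = res.importance()
        # gain of the single split is data dependent via bootstrap; recompute
        total = 0.0
        stack = [res.trees[0]]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                total += n.gain
                stack += [n.left, n.right]
        assert np.isclose(imp["importance"][0], total / 1)

    def test_informative_feature_ranks_first(self):
        wins = 0
        for seed in range(10):
            fm = _two_gaussians(n=60, p=8, d=2.5, seed=seed)
            res = RandomForestModel(fm, n_trees=200, seed=seed).fit()
            imp = res.importance()
            wins += int(imp["importance"].idxmax() == 0)
        assert wins >= 9


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_worked_example(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert np.isclose(auc, 0.75)

    def test_one_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 80))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        s = np.round(rng.uniform(size=n), 2)  # induce ties
        pts, auc = roc_auc(s, y)
        assert np.isclose(auc, roc_auc_score(y, s), atol=1e-12)
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]


class TestPermutation:
    def test_perfect_auc_gives_p_zero(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 10)
        s = y + rng.uniform(0, 0.1, size=20)
        _, _, p = permutation_pvalue(s, y, B=1000, seed=0)
        assert p == 0.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        s, y = rng.uniform(size=30), rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        p1 = permutation_pvalue(s, y, B=200, seed=5)[2]
        p2 = permutation_pvalue(s, y, B=200, seed=5)[2]
        assert p1 == p2

    def test_smoothed_variant(self):
        rng = np.random.default_rng(2)
        s, y = rng.uniform(size=30), np.repeat([0, 1], 15)
        _, null, p = permutation_pvalue(s, y, B=100, seed=0)
        _, _, ps = permutation_pvalue(s, y, B=100, seed=0, smoothed=True)
        assert np.isclose(ps, ((null > roc_auc(s, y)[1]).sum() + 1) / 101)
        assert p == (null > roc_auc(s, y)[1]).sum() / 100


class TestEvaluateProtocol:
    def test_stratified_fold_sizes_odd_to_training(self):
        fm = _two_gaussians(n=60, seed=6)
        fm = FeatureMatrix(fm.X[:55], fm.y[:55], fm.tags)  # 30 + 25
        ev = evaluate_protocol(fm, "stratified2fold", n_trees=20, B=50, seed=0)
        assert ev.fold_sizes["train"][0] == 15 and ev.fold_sizes["test"][0] == 15
        assert ev.fold_sizes["train"][1] == 13 and ev.fold_sizes["test"][1] == 12

    def test_loocv_aggregates_once(self):
        fm = _two_gaussians(n=16, p=4, d=3.0, seed=7)
        ev = evaluate_protocol(fm, "loocv", n_trees=20, B=50, seed=0)
        assert len(ev.scores) == 16
        assert ev.auc > 0.8  # strongly separated

    def test_unknown_scheme_error(self):
        with pytest.raises(ValueError, match="scheme"):
            evaluate_protocol(_two_gaussians(), "bootstrap632")

    def test_subsets_get_q_values(self):
        fm = _two_gaussians(n=40, p=6, d=3.0, seed=8)
        tags = (("s1", "RD", 0), ("s1", "RD", 1), ("s1", "JD", 0),
                ("s1", "JD", 1), ("s1", "volume", None), ("s2", "volume", None))
        fm = FeatureMatrix(fm.X, fm.y, tags)
        evals = evaluate_feature_subsets(fm, subsets=("all", "RD"), n_trees=20,
                                         B=50, seed=0)
        assert all(e.q_value is not None for e in evals)
        assert all(e.q_value >= e.p_value - 1e-12 for e in evals)


class TestImportanceToSurfaces:
    def test_zero_importance_zero_overlays(self, small_cohort):
        s = small_cohort.config.structures[0]
        nv = small_cohort.templates[s].n_vertices
        imp = pd.DataFrame({
            "feature": [f"{s}.RD.{i}" for i in range(nv)],
            "structure": s, "kind": "RD", "vertex": range(nv),
            "importance": 0.0, "n_split_nodes": 0,
        })
        overlays, summary = importance_to_surfaces(imp, small_cohort.templates)
        assert np.all(overlays[(s, "RD")].values == 0)

    def test_concentrated_importance_tops_region_table(self, small_cohort):
        s = small_cohort.config.structures[0]
        rows = []
        for struct, val in ((s, 1.0), ("other", 0.0)):
            for i in range(5):
                rows.append({"feature": f"{struct}.RD.{i}", "structure": struct,
                             "kind": "RD", "vertex": i, "importance": val,
                             "n_split_nodes": 1})
        templates = dict(small_cohort.templates)
        templates["other"] = small_cohort.templates[s]
        _, summary = importance_to_surfaces(pd.DataFrame(rows), templates)
        rd = summary[summary["kind"] == "RD"]
        assert rd.iloc[0]["structure"] == s

    def test_untagged_feature_error(self):
        imp = pd.DataFrame({"feature": ["x"], "structure": [""], "kind": ["RD"],
                            "vertex": [0], "importance": [1.0],
                            "n_split_nodes": [1]})
        with pytest.raises(ValueError):
            importance_to_surfaces(imp, {})


class TestFeatureMatrixIO:
    def test_csv_round_trip(self, tmp_path):
        fm = _two_gaussians(n=10, p=3, seed=9)
        df = fm.to_frame()
        p = tmp_path / "fm.csv"
        df.to_csv(p)
        back = FeatureMatrix.from_frame(pd.read_csv(p, index_col=0))
        assert np.allclose(back.X, fm.X)
        assert np.array_equal(back.y, fm.y)
        assert tuple(back.tags) == tuple(fm.tags)
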