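"""Random forest, MDI, cross-validation and recursive feature elimination."""

from fractions import Fraction

import numpy as np
import pytest

from gazestrat.forest import (
    ForestConfig,
    LabeledTable,
    RandomForest,
    cv_accuracy,
    gini,
    impurity_decrease,
    mdi,
    rfe,
    train_forest,
)


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((2, 1), 4 / 9)],
    )
    def test_closed_form_cases(self, counts, expected):
        assert gini(counts) == pytest.approx(expected, abs=1e-12)

    def test_range_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = rng.integers(2, 6)
            counts = rng.integers(1, 50, k)
            g = gini(counts)
            assert 0.0 <= g <= 1.0 - 1.0 / k + 1e-12

    def test_empty_node_errors(self):
        with pytest.raises(ValueError):
            gini((0, 0))


class TestImpurityDecrease:
    def test_perfect_split_of_balanced_node(self):
        assert impurity_decrease((5, 5), (5, 0), (0, 5)) == pytest.approx(0.5)

    def test_empty_child_errors(self):
        with pytest.raises(ValueError):
            impurity_decrease((5, 5), (5, 5), (0, 0))

    def test_count_mismatch_errors(self):
        with pytest.raises(ValueError):
            impurity_decrease((5, 5), (3, 0), (0, 5))

    def test_matches_exact_fraction_arithmetic_and_nonneg(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            parent = rng.integers(1, 30, 2)
            left = np.array([rng.integers(0, p + 1) for p in parent])
            right = parent - left
            if left.sum() == 0 or right.sum() == 0:
                continue

            def g(c):
                n = Fraction(int(sum(c)))
                return 1 - sum(Fraction(int(x)) ** 2 / n**2 for x in c)

            n, nl, nr = (Fraction(int(v.sum())) for v in (parent, left, right))
            exact = g(parent) - nl / n * g(left) - nr / n * g(right)
            ours = impurity_decrease(parent, left, right)
            assert ours == pytest.approx(float(exact), abs=1e-12)
            assert ours >= -1e-12


def _separable_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x_signal = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(8, 1, n // 2)])
    X = np.column_stack([x_signal, rng.normal(size=n)])
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    return LabeledTable(X=X, y=y, feature_names=("signal", "noise"))


class TestTrainForest:
    def test_separable_stump_perfect_training_accuracy(self):
        table = _separable_table()
        forest = train_forest(
            table, ForestConfig(n_trees=1, max_depth=1, max_features=2, seed=3)
        )
        assert (forest.predict(table.X) == table.y).all()

    def test_memorizes_training_points_without_bootstrap(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30).astype(str)
        table = LabeledTable(X=X, y=y, feature_names=("a", "b", "c"))
        forest = train_forest(
            table,
            ForestConfig(n_trees=1, bootstrap=False, max_features=3, seed=5),
        )
        assert (forest.predict(X) == y).all()

    def test_holdout_accuracy_on_separable_data(self):
        table = _separable_table(n=40, seed=6)
        holdout = _separable_table(n=40, seed=7)
        forest = train_forest(table, ForestConfig(n_trees=100, seed=8))
        acc = (forest.predict(holdout.X) == holdout.y).mean()
        assert acc >= 0.9

    def test_single_class_errors(self):
        X = np.random.default_rng(9).normal(size=(10, 2))
        with pytest.raises(ValueError, match="2 classes"):
            RandomForest(ForestConfig(n_trees=5)).fit(X, np.zeros(10))

    def test_deterministic_under_seed(self):
        table = _separable_table(seed=10)
        f1 = train_forest(table, ForestConfig(n_trees=20, seed=11))
        f2 = train_forest(table, ForestConfig(n_trees=20, seed=11))
        assert np.array_equal(
            f1.feature_importances(), f2.feature_importances()
        )
        assert (f1.predict(table.X) == f2.predict(table.X)).all()


def _mdi_oracle(forest, X, y):
    """Independent MDI recomputation: route the training data through each
    stored tree and re-derive every node's weighted impurity decrease."""
    classes = forest.classes_
    enc = np.searchsorted(classes, y)
    k = X.shape[1]
    totals = np.zeros((len(forest.trees_), k))
    for t, (feat, thr, left, right, leaf) in enumerate(forest.trees_):
        n = X.shape[0]

        def walk(node, idx):
            if leaf[node] >= 0:
                return
            f, th = feat[node], thr[node]
            go_left = X[idx, f] <= th
            li, ri = idx[go_left], idx[~go_left]

            def counts(ii):
                return np.bincount(enc[ii], minlength=classes.size)

            dec = impurity_decrease(counts(idx), counts(li), counts(ri))
            totals[t, f] += (idx.size / n) * dec
            walk(left[node], li)
            walk(right[node], ri)

        walk(0, np.arange(n))
    raw = totals.mean(axis=0)
    return raw / raw.sum()


class TestMdi:
    def test_single_stump_concentrates_importance(self):
        table = _separable_table()
        forest = train_forest(
            table,
            ForestConfig(n_trees=1, max_depth=1, max_features=2, bootstrap=False, seed=12),
        )
        imp = mdi(forest)
        assert imp[0] == pytest.approx(1.0)
        assert imp[1] == 0.0

    def test_sums_to_one(self, planted_table, forest_config):
        forest = train_forest(planted_table, forest_config)
        assert mdi(forest).sum() == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_labels_spread_importance(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(300, 6))
        y = rng.permutation(np.repeat(["A", "B"], 150))
        table = LabeledTable(X=X, y=y, feature_names=tuple("abcdef"))
        forest = train_forest(table, ForestConfig(n_trees=200, seed=14))
        imp = mdi(forest)
        assert imp.max() < 0.5
        assert (imp < 3 / 6).all() and (imp > 1 / (3 * 6) / 2).all()

    def test_planted_feature_ranks_first(self):
        rng = np.random.default_rng(15)
        n = 400
        y = np.repeat(["A", "B"], n // 2)
        X = rng.normal(size=(n, 7))
        X[:, 3] += np.where(y == "A", 2.0, -2.0)
        table = LabeledTable(X=X, y=y, feature_names=tuple("abcdefg"))
        forest = train_forest(table, ForestConfig(n_trees=200, seed=16))
        assert int(np.argmax(mdi(forest))) == 3

    def test_matches_independent_recomputation(self):
        """MDI equals a from-scratch tree walk on >= 20 random instances."""
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = int(rng.integers(20, 60))
            k = int(rng.integers(2, 5))
            X = rng.normal(size=(n, k))
            y = rng.integers(0, 2, n).astype(str)
            if len(np.unique(y)) < 2:
                continue
            table = LabeledTable(X=X, y=y, feature_names=tuple(f"f{i}" for i in range(k)))
            forest = train_forest(
                table,
                ForestConfig(n_trees=3, bootstrap=False, max_features=k, seed=trial),
            )
            ours = forest.feature_importances()
            oracle = _mdi_oracle(forest, X, y)
            assert np.allclose(ours, oracle, atol=1e-9)


class TestCvAccuracy:
    def test_perfectly_separable(self):
        table = _separable_table(n=60, seed=18)
        acc = cv_accuracy(table, ForestConfig(n_trees=30, seed=19), folds=10)
        assert acc == pytest.approx(1.0)

    def test_fold_sizes_balanced(self):
        from gazestrat.forest import _fold_assignments

        rng = np.random.default_rng(20)
        y = rng.permutation(np.repeat(["A", "B", "C"], [47, 31, 22]))
        fold_of = _fold_assignments(y, 10, rng, stratified=True)
        sizes = np.bincount(fold_of, minlength=10)
        assert sizes.max() - sizes.min() <= 1
        for cls in "ABC":
            cls_sizes = np.bincount(fold_of[y == cls], minlength=10)
            assert cls_sizes.max() - cls_sizes.min() <= 1

    def test_small_class_falls_back_unstratified(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 2))
        y = np.array(["A"] * 36 + ["B"] * 4)
        table = LabeledTable(X=X, y=y, feature_names=("a", "b"))
        with pytest.warns(UserWarning, match="unstratified"):
            cv_accuracy(table, ForestConfig(n_trees=5, seed=22), folds=10)


class TestRfe:
    def test_single_feature_trivial(self):
        table = _separable_table()
        one = LabeledTable(
            X=table.X[:, :1], y=table.y, feature_names=("signal",)
        )
        trace = rfe(one, ForestConfig(n_trees=10, seed=23), folds=5)
        assert len(trace.iterations) == 1
        assert trace.optimal_subset == ("signal",)

    def test_nested_and_complete(self, planted_table):
        trace = rfe(planted_table, ForestConfig(n_trees=50, seed=24), folds=5)
        assert len(trace.iterations) == len(planted_table.feature_names)
        sets = [set(it.features) for it in trace.iterations]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller < bigger
        sizes = [len(s) for s in sets]
        assert sizes == list(range(7, 0, -1))

    def test_accuracy_plateau_with_top_features(self, planted_table):
        """CV accuracy is near its max once the top two features survive."""
        trace = rfe(planted_table, ForestConfig(n_trees=50, seed=25), folds=5)
        accs = [it.cv_accuracy for it in trace.iterations]
        two_feature_acc = accs[-2]
        assert two_feature_acc >= max(accs) - 0.02


class TestSklearnCrossCheck:
    """Our forest should score close to scikit-learn on matched settings."""

    @pytest.mark.parametrize("seed", [30, 31, 32])
    def test_cv_accuracy_close_to_reference(self, seed):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        rng = np.random.default_rng(seed)
        n = 200
        y = np.repeat(["A", "B"], n // 2)
        X = rng.normal(size=(n, 4))
        X[:, 0] += np.where(y == "A", 1.5, -1.5)
        X[:, 1] += np.where(y == "A", -1.0, 1.0)
        table = LabeledTable(X=X, y=y, feature_names=("a", "b", "c", "d"))
        ours = cv_accuracy(table, ForestConfig(n_trees=100, seed=seed), folds=5)
        ref = cross_val_score(
            RandomForestClassifier(
                n_estimators=100, max_features="sqrt", random_state=seed
            ),
            X,
            y,
            cv=StratifiedKFold(5, shuffle=True, random_state=seed),
        ).mean()
        assert abs(ours - ref) < 0.05
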