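import numpy as np
import pandas as pd
import pytest

from tissueformer.benchmarks import (
    GroupFeatureMatrix,
    LogZTransform,
    cell_type_kneighbors_predict,
    cell_type_modal_predict,
    fit_feature_classifier,
    pseudobulk_features,
    type_composition_features,
)
from tissueformer.data import CellTable, ValidationError
from tissueformer.grouping import CellGroup


def group_of(idx, label="A"):
    return CellGroup(np.asarray(idx), seed_index=idx[0], label=label, brain_id="b")


def table_from_counts(counts, **kw):
    counts = np.asarray(counts)
    n = len(counts)
    defaults = dict(
        gene_ids=[f"g{i}" for i in range(counts.shape[1])],
        xy=np.zeros((n, 2)),
        brain_id=["b"] * n,
    )
    defaults.update(kw)
    return CellTable(counts=counts, **defaults)


class TestPseudobulk:
    def test_mean_arithmetic(self):
        t = table_from_counts([[0, 2], [4, 0]])
        feats, _ = pseudobulk_features([group_of([0, 1])], t, apply_transform=False)
        np.testing.assert_array_equal(feats.features, [[2.0, 1.0]])

    def test_identical_cells_give_that_cells_counts(self):
        t = table_from_counts([[3, 1, 4], [3, 1, 4]])
        feats, _ = pseudobulk_features([group_of([0, 1])], t, apply_transform=False)
        np.testing.assert_array_equal(feats.features, [[3.0, 1.0, 4.0]])

    def test_training_columns_are_z_scored(self):
        rng = np.random.default_rng(0)
        t = table_from_counts(rng.integers(0, 20, size=(60, 5)))
        groups = [group_of([i, i + 1]) for i in range(0, 58, 2)]
        feats, _ = pseudobulk_features(groups, t)
        assert np.abs(feats.features.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(feats.features.std(axis=0), 1.0, atol=1e-10)

    def test_held_out_rows_use_training_moments(self):
        rng = np.random.default_rng(1)
        t = table_from_counts(rng.integers(0, 20, size=(40, 4)))
        tr = [group_of([i]) for i in range(20)]
        te = [group_of([i]) for i in range(20, 40)]
        _, tf = pseudobulk_features(tr, t)
        fte, _ = pseudobulk_features(te, t, transform=tf)
        lx = np.log1p(t.counts_dense()[20:].astype(float))
        np.testing.assert_allclose(fte.features, (lx - tf.mean) / tf.std)


class TestTypeComposition:
    @pytest.fixture
    def typed_table(self):
        return table_from_counts(
            np.ones((6, 2), int),
            type_h3=pd.Categorical(["X", "X", "Y", "Z", "Z", "Z"]),
            area_label=pd.Categorical(["A"] * 6),
        )

    def test_histogram_values(self, typed_table):
        feats = type_composition_features([group_of([0, 1, 2, 3])], typed_table)
        np.testing.assert_allclose(feats.features, [[0.5, 0.25, 0.25]])

    def test_single_type_group_is_one_hot(self, typed_table):
        feats = type_composition_features([group_of([3, 4, 5])], typed_table)
        np.testing.assert_array_equal(feats.features, [[0.0, 0.0, 1.0]])

    def test_rows_sum_to_one_for_random_groups(self, typed_table):
        rng = np.random.default_rng(2)
        groups = [group_of(list(rng.choice(6, size=rng.integers(1, 6), replace=False))) for _ in range(1000)]
        feats = type_composition_features(groups, typed_table)
        np.testing.assert_array_equal(feats.features.sum(axis=1), np.ones(1000))

    def test_absent_type_level_errors(self):
        t = table_from_counts(np.ones((2, 2), int))
        with pytest.raises(ValidationError):
            type_composition_features([group_of([0])], t)


class TestFeatureClassifier:
    def _gaussian_features(self, rng, sep=6.0, n=120):
        x = rng.normal(size=(n, 4))
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        x[y == "B", 0] += sep
        return x, y

    def test_separable_gaussians_classified_nearly_perfectly(self):
        rng = np.random.default_rng(0)
        xtr, ytr = self._gaussian_features(rng)
        xte, yte = self._gaussian_features(rng)
        clf = fit_feature_classifier(GroupFeatureMatrix(xtr, "pseudobulk", ytr))
        assert (clf.predict(xte) == yte).mean() >= 0.99

    def test_label_shuffle_scores_near_chance(self):
        rng = np.random.default_rng(1)
        xtr, ytr = self._gaussian_features(rng, n=400)
        ytr = rng.permutation(ytr)
        xte, yte = self._gaussian_features(rng, n=400)
        yte = rng.permutation(yte)
        clf = fit_feature_classifier(GroupFeatureMatrix(xtr, "pseudobulk", ytr))
        acc = (clf.predict(xte) == yte).mean()
        # binomial 99.9% band around 0.5 at n=400
        assert abs(acc - 0.5) < 3.3 * np.sqrt(0.25 / 400)

    def test_random_forest_same_seed_same_predictions(self):
        rng = np.random.default_rng(2)
        xtr, ytr = self._gaussian_features(rng, sep=1.0)
        a = fit_feature_classifier(
            GroupFeatureMatrix(xtr, "pseudobulk", ytr), "random_forest", rng_seed=7
        )
        b = fit_feature_classifier(
            GroupFeatureMatrix(xtr, "pseudobulk", ytr), "random_forest", rng_seed=7
        )
        xte, _ = self._gaussian_features(rng, sep=1.0)
        assert np.array_equal(a.predict(xte), b.predict(xte))

    def test_single_class_training_rejected(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValidationError):
            fit_feature_classifier(GroupFeatureMatrix(x, "pseudobulk", np.array(["A"] * 5)))

    def test_paper_hyperparameters_are_defaults(self):
        rng = np.random.default_rng(3)
        xtr, ytr = self._gaussian_features(rng)
        rf = fit_feature_classifier(
            GroupFeatureMatrix(xtr, "pseudobulk", ytr), "random_forest"
        )
        assert (rf.n_estimators, rf.max_depth, rf.max_features) == (200, 15, 0.33)
        assert (rf.min_samples_split, rf.min_samples_leaf) == (5, 2)
        lr = fit_feature_classifier(GroupFeatureMatrix(xtr, "pseudobulk", ytr))
        assert lr.penalty is None and lr.solver == "lbfgs"


class TestCellTypeHeuristics:
    @pytest.fixture
    def train_table(self):
        return table_from_counts(
            np.array([[9, 0], [8, 1], [0, 9], [1, 8], [5, 5]]),
            type_h3=pd.Categorical(["X", "X", "Y", "Y", "Y"]),
            area_label=pd.Categorical(["A", "A", "B", "A", "B"]),
        )

    def test_type_seen_in_single_area_predicts_it(self, train_table):
        test = table_from_counts(np.ones((2, 2), int), type_h3=pd.Categorical(["X", "X"]))
        assert list(cell_type_modal_predict(train_table, test)) == ["A", "A"]

    def test_split_type_takes_mode(self):
        tr = table_from_counts(
            np.ones((4, 2), int),
            type_h3=pd.Categorical(["X"] * 4),
            area_label=pd.Categorical(["A", "A", "A", "B"]),
        )
        te = table_from_counts(np.ones((1, 2), int), type_h3=pd.Categorical(["X"]))
        assert cell_type_modal_predict(tr, te)[0] == "A"

    def test_unseen_type_falls_back_to_global_mode(self, train_table):
        test = table_from_counts(np.ones((1, 2), int), type_h3=pd.Categorical(["Q"]))
        assert cell_type_modal_predict(train_table, test)[0] == "A"  # global mode

    def test_kneighbors_exact_duplicate_wins_at_k1(self, train_table):
        test = table_from_counts(
            np.array([[0, 9]]), type_h3=pd.Categorical(["Y"])
        )
        assert cell_type_kneighbors_predict(train_table, test, k=1)[0] == "B"

    def test_kneighbors_unanimous_neighbors_for_any_k(self):
        tr = table_from_counts(
            np.array([[9, 0], [8, 1], [7, 2]]),
            type_h3=pd.Categorical(["X"] * 3),
            area_label=pd.Categorical(["A"] * 3),
        )
        te = table_from_counts(np.array([[9, 1]]), type_h3=pd.Categorical(["X"]))
        for k in (1, 2, 3):
            assert cell_type_kneighbors_predict(tr, te, k=k)[0] == "A"

    def test_kneighbors_warns_when_type_has_too_few_cells(self, train_table):
        test = table_from_counts(np.ones((1, 2), int), type_h3=pd.Categorical(["X"]))
        with pytest.warns(UserWarning, match="only"):
            cell_type_kneighbors_predict(train_table, test, k=10)

    def test_kneighbors_agrees_with_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(4)
        n_tr, n_te, k = 300, 100, 5
        tr = table_from_counts(
            rng.integers(0, 15, size=(n_tr, 6)),
            type_h3=pd.Categorical(rng.choice(["X", "Y"], n_tr)),
            area_label=pd.Categorical(rng.choice(["A", "B", "C"], n_tr)),
        )
        te = table_from_counts(
            rng.integers(0, 15, size=(n_te, 6)),
            type_h3=pd.Categorical(rng.choice(["X", "Y"], n_te)),
        )
        got = cell_type_kneighbors_predict(tr, te, k=k)
        # independent oracle: full distance sort in the transformed space
        tf = LogZTransform.fit(tr.counts_dense())
        xtr, xte = tf(tr.counts_dense()), tf(te.counts_dense())
        types_tr = np.asarray(tr.type_h3).astype(str)
        areas = np.asarray(tr.area_label).astype(str)
        for i in range(n_te):
            t = str(np.asarray(te.type_h3)[i])
            pool = np.nonzero(types_tr == t)[0]
            d = np.linalg.norm(xtr[pool] - xte[i], axis=1)
            near = pool[np.argsort(d, kind="stable")[:k]]
            vals, cnt = np.unique(areas[near], return_counts=True)
            assert got[i] == vals[np.argmax(cnt)], i
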