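import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from fadel import (
    DEFAULT_PLAN,
    FadelClassifier,
    FeatureView,
    RoutingPlan,
    assemble_meta_features,
    build_views,
    confusion,
    fit_fadel,
    fit_meta,
    generate,
    load_model,
    make_scenario,
    save_model,
    stratified_split,
    vote,
)
from fadel.base import base_probabilities, fit_base_models
from fadel.discretize import CartBinner


def _views_of(ds):
    binner = CartBinner().fit(ds.X[ds.flagged_features], ds.y)
    discs = {d.feature_name: d for d in binner.discretizers_}
    nd, fd, _ = build_views(ds, discs)
    return nd, fd


class TestAssembleMetaFeatures:
    def test_direct_mode_equals_in_sample_probabilities(self, separable_ds):
        nd, fd = _views_of(separable_ds)
        plan = RoutingPlan((("stub", "ND"), ("stub", "FD")))
        meta, learners = assemble_meta_features(
            nd, fd, separable_ds.y, plan, seeds=[0, 1], mode="direct"
        )
        np.testing.assert_allclose(meta, base_probabilities(learners, nd, fd))

    def test_out_of_fold_breaks_memorization(self, clinical_ds):
        """In-sample (direct) meta features of a flexible learner carry
        training optimism that out-of-fold assembly removes."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        y_noise = rng.permutation(clinical_ds.y)  # no signal left
        nd, fd = _views_of(clinical_ds)
        plan = RoutingPlan((("xgboost", "ND"),))
        direct, _ = assemble_meta_features(nd, fd, y_noise, plan, [0], mode="direct")
        oof, _ = assemble_meta_features(
            nd, fd, y_noise, plan, [0], mode="out_of_fold", k=2, fold_seed=0
        )
        auc_direct = roc_auc_score(y_noise, direct[:, 0])
        auc_oof = roc_auc_score(y_noise, oof[:, 0])
        assert auc_direct > 0.9  # memorized
        assert auc_oof < auc_direct - 0.2  # leakage removed

    def test_determinism(self, separable_ds):
        nd, fd = _views_of(separable_ds)
        kw = dict(plan=DEFAULT_PLAN, seeds=[0, 1, 2, 3], mode="out_of_fold", k=3, fold_seed=5)
        m1, _ = assemble_meta_features(nd, fd, separable_ds.y, **kw)
        m2, _ = assemble_meta_features(nd, fd, separable_ds.y, **kw)
        np.testing.assert_array_equal(m1, m2)

    def test_fold_validation(self, separable_ds):
        nd, fd = _views_of(separable_ds)
        with pytest.raises(ValueError, match="k >= 2"):
            assemble_meta_features(nd, fd, separable_ds.y, DEFAULT_PLAN, mode="out_of_fold", k=1)
        y_few = np.zeros(separable_ds.n_rows, dtype=int)
        y_few[:2] = 1
        with pytest.raises(ValueError, match="members per class"):
            assemble_meta_features(nd, fd, y_few, DEFAULT_PLAN, mode="out_of_fold", k=5)


class TestMetaForestAndVote:
    def test_separable_meta_feature_training_accuracy(self):
        rng = np.random.default_rng(1)
        y = (rng.random(200) < 0.2).astype(int)
        meta = rng.random((200, 4)) * 0.2
        meta[:, 0] = np.where(y == 1, 0.9, 0.1)  # column 0 separates perfectly
        forest = fit_meta(meta, y, n_trees=20, seed=0)
        labels, _ = vote(forest, meta)
        assert (labels == y).all()

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_meta(np.random.rand(10, 4), np.zeros(10, dtype=int))

    def test_single_tree_reduction(self):
        rng = np.random.default_rng(2)
        y = (rng.random(100) < 0.3).astype(int)
        meta = np.column_stack([np.where(y == 1, 0.8, 0.2)] * 4) + rng.normal(0, 0.01, (100, 4))
        forest = fit_meta(meta, y, n_trees=1, seed=0)
        labels, _ = vote(forest, meta)
        tree_pred = forest.estimators_[0].predict(meta)
        np.testing.assert_array_equal(labels, tree_pred.astype(int))

    def test_majority_and_tie_break(self):
        # hand-built 2-tree forest disagreeing on a probe: tie goes negative
        X0 = np.array([[0.0], [1.0]])
        t_pos = DecisionTreeClassifier(random_state=0).fit(X0, [0, 1])
        t_neg = DecisionTreeClassifier(random_state=0).fit(X0, [1, 0])
        forest = RandomForestClassifier(n_estimators=2, bootstrap=False, random_state=0)
        forest.fit(np.array([[0.0], [1.0], [0.2], [0.8]]), [0, 1, 0, 1])
        forest.estimators_ = [t_pos, t_neg]
        labels, scores = vote(forest, np.array([[1.0]]))
        assert labels[0] == 0  # 1-1 split resolves to the negative class
        assert 0 <= scores[0] <= 1

    def test_vote_label_requires_strict_majority(self):
        rng = np.random.default_rng(3)
        y = (rng.random(300) < 0.1).astype(int)
        meta = np.where(y[:, None] == 1, 0.7, 0.3) + rng.normal(0, 0.2, (300, 4))
        meta = np.clip(meta, 0, 1)
        forest = fit_meta(meta, y, n_trees=11, seed=1)
        labels, _ = vote(forest, meta)
        votes = np.stack([t.predict(meta) for t in forest.estimators_])
        n_pos = (votes == 1).sum(axis=0)
        np.testing.assert_array_equal(labels == 1, n_pos * 2 > 11)

    def test_tree_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        y = (rng.random(100) < 0.3).astype(int)
        meta = np.clip(np.where(y[:, None] == 1, 0.7, 0.3) + rng.normal(0, 0.1, (100, 4)), 0, 1)
        forest = fit_meta(meta, y, n_trees=15, seed=2)
        labels1, scores1 = vote(forest, meta)
        rng.shuffle(forest.estimators_)
        labels2, scores2 = vote(forest, meta)
        np.testing.assert_array_equal(labels1, labels2)
        np.testing.assert_allclose(scores1, scores2)


@pytest.fixture(scope="module")
def fitted(separable_ds):
    sp = stratified_split(separable_ds, 0.8, seed=1)
    model = FadelClassifier(n_folds=3, random_state=0).fit(sp.train, sp.train.y)
    return model, sp


class TestFadelClassifier:
    def test_separable_held_out_performance(self, fitted):
        model, sp = fitted
        c = confusion(sp.test.y, model.predict(sp.test.X))
        assert c.fn == 0  # recall 1.0
        assert c.tn / (c.tn + c.fp) >= 0.99

    def test_training_rows_recalled(self, fitted):
        model, sp = fitted
        pred = model.predict(sp.train.X)
        assert pred[sp.train.y == 1].mean() == 1.0

    def test_refit_same_seed_identical_predictions(self, separable_ds):
        sp = stratified_split(separable_ds, 0.8, seed=1)
        p1 = FadelClassifier(n_folds=3, random_state=9).fit(sp.train, sp.train.y).decision_scores(sp.test.X)
        p2 = FadelClassifier(n_folds=3, random_state=9).fit(sp.train, sp.train.y).decision_scores(sp.test.X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_row_and_out_of_range_input(self, fitted):
        model, sp = fitted
        row = sp.test.X.iloc[:1].copy()
        labels, scores = model.predict_with_scores(row)
        assert labels.shape == (1,) and 0 <= scores[0] <= 1
        far = row * 1e8
        labels2, _ = model.predict_with_scores(far)
        assert labels2.shape == (1,)

    def test_missing_column_raises_schema_error(self, fitted):
        model, sp = fitted
        with pytest.raises(ValueError, match="missing model columns"):
            model.predict(sp.test.X.drop(columns=[sp.test.X.columns[0]]))

    def test_scores_valid_and_vote_coherent(self, fitted):
        model, sp = fitted
        labels, scores = model.predict_with_scores(sp.test.X)
        assert np.all((scores >= 0) & (scores <= 1))
        votes = np.stack(
            [t.predict(model.base_probabilities_of(sp.test.X)) for t in model.meta_forest_.estimators_]
        )
        n_pos = (votes == 1).sum(axis=0)
        T = len(model.meta_forest_.estimators_)
        np.testing.assert_array_equal(labels == 1, n_pos * 2 > T)

    def test_sklearn_clone_and_params(self):
        model = FadelClassifier(n_meta_trees=7, random_state=3)
        cloned = clone(model)
        assert cloned.get_params()["n_meta_trees"] == 7

    def test_no_flagged_features_fails_fast(self):
        X = pd.DataFrame({"f": ["a", "b", "a", "b"]})
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="discretization"):
            FadelClassifier(categorical_features=["f"]).fit(X, y)

    def test_perfect_oracle_meta_column(self):
        """With every base probability replaced by a perfect oracle, the
        meta layer reaches G-mean 1 on separable data."""
        rng = np.random.default_rng(5)
        y = (rng.random(400) < 0.1).astype(int)
        oracle = np.tile(np.where(y == 1, 0.99, 0.01)[:, None], (1, 4))
        forest = fit_meta(oracle, y, n_trees=50, seed=0)
        labels, _ = vote(forest, oracle)
        c = confusion(y, labels)
        assert c.fn == 0 and c.fp == 0


class TestPersistence:
    def test_archive_round_trip(self, tmp_path, separable_ds):
        sp = stratified_split(separable_ds, 0.8, seed=2)
        model = fit_fadel(sp.train, {"n_folds": 3, "random_state": 1})
        d = str(tmp_path / "model")
        save_model(model, d)
        back = load_model(d)
        np.testing.assert_allclose(
            model.decision_scores(sp.test.X), back.decision_scores(sp.test.X), atol=1e-9
        )
        np.testing.assert_array_equal(model.predict(sp.test.X), back.predict(sp.test.X))

    def test_version_check(self, tmp_path, separable_ds):
        import json, os

        sp = stratified_split(separable_ds, 0.8, seed=2)
        model = fit_fadel(sp.train, {"n_folds": 3, "random_state": 1})
        d = str(tmp_path / "model")
        save_model(model, d)
        mpath = os.path.join(d, "manifest.json")
        doc = json.load(open(mpath))
        doc["format_version"] = 99
        json.dump(doc, open(mpath, "w"))
        with pytest.raises(ValueError, match="format version"):
            load_model(d)
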