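import numpy as np
import pandas as pd
import pytest

from fadel import (
    DEFAULT_PLAN,
    FeatureView,
    OrderedTargetEncoder,
    RoutingPlan,
    StumpAdaBoostClassifier,
    adaboost_round,
    base_probabilities,
    build_views,
    fit_base_models,
    target_encode_fit_transform,
)
from fadel.base import logit, sigmoid
from fadel.discretize import CartBinner


class TestTargetEncoding:
    def test_first_occurrence_is_prior(self):
        enc, _ = target_encode_fit_transform(["A"], [1], a=1, p=0.5)
        assert enc[0] == 0.5

    def test_hand_worked_running_means(self):
        enc, _ = target_encode_fit_transform(["A", "A", "A"], [1, 0, 0], a=1, p=0.5)
        np.testing.assert_allclose(enc, [0.5, (1 + 0.5) / 2, (1 + 0 + 0.5) / 3])
        enc2, _ = target_encode_fit_transform(["A", "A", "A"], [1, 1, 0], a=1, p=0.5)
        assert enc2[2] == pytest.approx((2 + 0.5) / 3)

    def test_leave_one_out_property(self):
        """A sample's own label never contributes to its encoding."""
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, 50)
        y = rng.integers(0, 2, 50).astype(float)
        enc_a, _ = target_encode_fit_transform(codes, y, a=1, p=0.3, order_seed=9)
        i = 17
        y_flipped = y.copy()
        y_flipped[i] = 1 - y_flipped[i]
        enc_b, _ = target_encode_fit_transform(codes, y_flipped, a=1, p=0.3, order_seed=9)
        assert enc_a[i] == enc_b[i]

    def test_transform_uses_full_training_stats(self):
        enc = OrderedTargetEncoder(a=1.0, prior=0.5, order_seed=None)
        enc.fit_transform(np.array([["A"], ["A"], ["B"]]), [1, 1, 0])
        out = enc.transform(np.array([["A"], ["B"], ["C"]]))
        np.testing.assert_allclose(out[:, 0], [(2 + 0.5) / 3, (0 + 0.5) / 2, 0.5])

    def test_zero_smoothing_warns_and_uses_prior(self):
        enc = OrderedTargetEncoder(a=0.0, prior=0.25, order_seed=None)
        with pytest.warns(RuntimeWarning):
            out = enc.fit_transform(np.array([["A"]]), [1])
        assert out[0, 0] == 0.25

    def test_encoder_json_round_trip(self):
        enc = OrderedTargetEncoder(a=1.0, prior=0.2, order_seed=3)
        enc.fit_transform(np.array([[1, 2], [1, 3], [2, 2]]), [1, 0, 1])
        back = OrderedTargetEncoder.from_dict(enc.to_dict())
        probe = np.array([[1, 2], [2, 3]])
        np.testing.assert_allclose(enc.transform(probe), back.transform(probe))


class TestAdaBoostRound:
    def test_one_misclassified_hand_example(self):
        w = [0.25] * 4
        eps, alpha, w_next = adaboost_round(w, [0, 0, 0, 1], [0, 0, 0, 0])
        assert eps == pytest.approx(0.25)
        assert alpha == pytest.approx(0.5 * np.log(3))
        np.testing.assert_allclose(w_next, [1 / 6, 1 / 6, 1 / 6, 1 / 2])

    def test_half_error_fixed_point(self):
        w = [0.5, 0.5]
        eps, alpha, w_next = adaboost_round(w, [1, 0], [0, 0])
        assert eps == pytest.approx(0.5)
        assert alpha == 0.0
        np.testing.assert_allclose(w_next, w)

    def test_perfect_learner_alpha_clipped(self):
        eps, alpha, _ = adaboost_round([0.5, 0.5], [0, 1], [0, 1])
        assert eps == 0.0
        assert alpha == pytest.approx(0.5 * np.log((1 - 1e-10) / 1e-10))

    def test_weight_conservation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = rng.dirichlet(np.ones(10))
            h = rng.integers(0, 2, 10)
            y = rng.integers(0, 2, 10)
            if (w @ (h != y)) in (0.0,):
                continue
            _, _, w_next = adaboost_round(w, h, y)
            assert abs(w_next.sum() - 1) < 1e-12

    def test_misclassified_weight_strictly_increases(self):
        w = [0.25] * 4
        _, _, w_next = adaboost_round(w, [0, 0, 0, 1], [0, 0, 0, 0])
        assert w_next[3] > 0.25


class TestStumpAdaBoost:
    def test_separable_training_fit(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        clf = StumpAdaBoostClassifier(n_estimators=10).fit(X, y)
        np.testing.assert_array_equal(clf.predict(X), y)
        # perfect first stump halts boosting with a clipped alpha
        assert len(clf.alphas_) == 1

    def test_probability_is_sigmoid_of_score(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0], [5.0], [5.5]])
        y = np.array([0, 0, 1, 1, 0, 1])
        clf = StumpAdaBoostClassifier(n_estimators=20).fit(X, y)
        s = clf.decision_function(X)
        np.testing.assert_allclose(clf.predict_proba(X)[:, 1], sigmoid(s))

    def test_json_round_trip_byte_identical(self):
        import json

        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + rng.normal(scale=0.5, size=60) > 0).astype(int)
        a = StumpAdaBoostClassifier(n_estimators=15, random_state=0).fit(X, y)
        b = StumpAdaBoostClassifier(n_estimators=15, random_state=0).fit(X, y)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())
        back = StumpAdaBoostClassifier.from_dict(a.to_dict())
        np.testing.assert_allclose(back.decision_function(X), a.decision_function(X))


class TestViewsAndRouting:
    def _views(self, ds):
        binner = CartBinner().fit(ds.X[ds.flagged_features], ds.y)
        discs = {d.feature_name: d for d in binner.discretizers_}
        return build_views(ds, discs)

    def test_view_shapes_and_row_order(self, clinical_ds):
        nd, fd, _ = self._views(clinical_ds)
        assert nd.n_rows == fd.n_rows == clinical_ds.n_rows
        n_flagged = len(clinical_ds.flagged_features)
        assert fd.frame.shape[1] == n_flagged
        # row identity: discretizing ND's flagged columns reproduces FD
        assert list(nd.frame.index) == list(fd.frame.index)

    def test_fd_entries_are_interval_indices(self, clinical_ds):
        nd, fd, _ = self._views(clinical_ds)
        assert fd.frame.to_numpy().min() >= 1

    def test_view_tag_mismatch_raises(self, separable_ds):
        nd, fd, _ = self._views(separable_ds)
        plan = RoutingPlan((("stub", "ND"), ("stub", "FD")))
        learners = fit_base_models(nd, fd, separable_ds.y, plan, seeds=[0, 1])
        with pytest.raises(ValueError, match="view-tag mismatch"):
            learners[0].probability(fd)

    def test_empty_fd_view_fails_fast(self):
        nd = FeatureView("ND", pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}))
        fd = FeatureView("FD", pd.DataFrame(index=range(4)))
        with pytest.raises(ValueError, match="no columns"):
            fit_base_models(nd, fd, np.array([0, 1, 0, 1]), DEFAULT_PLAN)


class TestBaseLayer:
    def test_sigmoid_logit_closed_forms(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(np.log(3)) == pytest.approx(0.75)
        assert logit(0.75) == pytest.approx(np.log(3))

    def test_separable_training_recall_every_slot(self, separable_ds):
        ds = separable_ds
        binner = CartBinner().fit(ds.X[ds.flagged_features], ds.y)
        discs = {d.feature_name: d for d in binner.discretizers_}
        nd, fd, _ = build_views(ds, discs)
        learners = fit_base_models(nd, fd, ds.y, DEFAULT_PLAN, seeds=[0, 1, 2, 3])
        P = base_probabilities(learners, nd, fd)
        assert P.shape == (ds.n_rows, 4)
        assert np.all((P > 0) & (P < 1))
        for m in range(4):
            pred = (P[:, m] > 0.5).astype(int)
            recall = pred[ds.y == 1].mean()
            assert recall == 1.0, f"slot {m} training recall {recall}"

    def test_label_shuffled_probabilities_near_prevalence(self, clinical_ds):
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(clinical_ds.y)
        ds = clinical_ds
        binner = CartBinner().fit(ds.X[ds.flagged_features], y_perm)
        discs = {d.feature_name: d for d in binner.discretizers_}
        nd, fd, _ = build_views(ds, discs)
        learners = fit_base_models(nd, fd, y_perm, DEFAULT_PLAN, seeds=[0, 1, 2, 3])
        P = base_probabilities(learners, nd, fd)
        prevalence = y_perm.mean()
        assert abs(P.mean() - prevalence) < 0.05

    def test_stub_contract_equivalence(self, separable_ds):
        """The slot contract runs unchanged with a plain logistic stub."""
        ds = separable_ds
        binner = CartBinner().fit(ds.X[ds.flagged_features], ds.y)
        discs = {d.feature_name: d for d in binner.discretizers_}
        nd, fd, _ = build_views(ds, discs)
        plan = RoutingPlan((("stub", "ND"), ("stub", "ND"), ("stub", "FD"), ("stub", "FD")))
        learners = fit_base_models(nd, fd, ds.y, plan, seeds=[0, 1, 2, 3])
        P = base_probabilities(learners, nd, fd)
        np.testing.assert_allclose(P, sigmoid(logit(P)), atol=1e-9)
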