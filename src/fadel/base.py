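"""Four-slot base-model layer with feature-type routing.

Two feature views of the same rows are built: the non-discretized (ND) view
keeps raw continuous columns, the feature-discretized (FD) view holds 1-based
interval indices of the flagged columns.  Categorical columns, having one
natural form, pass through to both views (ordinal-coded for the numeric
learners).  The default routing plan mirrors the framework's layout —

    slot 1: gradient boosting (XGBoost)            <- ND
    slot 2: gradient boosting (LightGBM)           <- ND
    slot 3: ordered target encoding + boosted GBDT <- FD
    slot 4: AdaBoost over depth-1 stumps           <- FD

Each slot learner exposes the same contract: ``fit(view, y)``, a probability
``p = sigmoid(raw_score)`` and the raw score ``logit(p)``.  Slot order is
fixed once the plan is built; it defines the meta-feature layout downstream.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .data import TabularDataset
from .discretize import FeatureDiscretizer, transform_dataset
from .encoding import OrderedTargetEncoder

__all__ = [
    "FeatureView",
    "RoutingPlan",
    "DEFAULT_PLAN",
    "sigmoid",
    "logit",
    "adaboost_round",
    "StumpAdaBoostClassifier",
    "build_views",
    "make_slot_learner",
    "fit_base_models",
    "base_probabilities",
]

_EPS_P = 1e-12
_ALPHA_EPS_MIN = 1e-10


def sigmoid(s):
    return 1.0 / (1.0 + np.exp(-np.asarray(s, dtype=float)))


def logit(p):
    p = np.clip(np.asarray(p, dtype=float), _EPS_P, 1 - _EPS_P)
    return np.log(p / (1 - p))


# ---------------------------------------------------------------------------
# Feature views & routing
# ---------------------------------------------------------------------------

@dataclass
class FeatureView:
    """One representation (ND or FD) of a dataset's rows."""

    tag: str  # "ND" | "FD"
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tag not in ("ND", "FD"):
            raise ValueError(f"view tag must be 'ND' or 'FD', got {self.tag!r}")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


@dataclass(frozen=True)
class RoutingPlan:
    """Ordered (learner kind, view tag) slots; order fixes the meta layout."""

    slots: tuple = (
        ("xgboost", "ND"),
        ("lightgbm", "ND"),
        ("target_encoded_gbdt", "FD"),
        ("adaboost", "FD"),
    )

    def __post_init__(self) -> None:
        for kind, tag in self.slots:
            if tag not in ("ND", "FD"):
                raise ValueError(f"slot ({kind!r}, {tag!r}): bad view tag")

    @property
    def n_slots(self) -> int:
        return len(self.slots)


DEFAULT_PLAN = RoutingPlan()


def build_views(
    ds: TabularDataset,
    discretizers: dict[str, FeatureDiscretizer],
    category_levels: dict[str, list] | None = None,
) -> tuple[FeatureView, FeatureView, dict[str, list]]:
    """Build the ND and FD views of a dataset.

    ND = raw continuous columns + ordinal-coded categoricals;
    FD = interval indices of flagged columns + the same categorical codes.
    Returns the two views plus the categorical level tables (fit them on
    training data, pass them back in at predict time).
    """
    if category_levels is None:
        category_levels = {
            name: sorted(map(str, ds.X[name].unique()))
            for name in ds.categorical_features
        }
    cat_codes = {}
    for name in ds.categorical_features:
        levels = {lv: i for i, lv in enumerate(category_levels[name])}
        cat_codes[name] = (
            ds.X[name].astype(str).map(lambda v: levels.get(v, -1)).to_numpy()
        )

    nd_cols = {}
    for s in ds.schema:
        if s.kind == "continuous":
            nd_cols[s.name] = ds.X[s.name].to_numpy(dtype=float)
        else:
            nd_cols[s.name] = cat_codes[s.name]
    nd = FeatureView("ND", pd.DataFrame(nd_cols, index=ds.X.index))

    fd_frame = transform_dataset(ds, discretizers)
    for name in ds.categorical_features:
        fd_frame[name] = cat_codes[name]
    fd = FeatureView("FD", fd_frame)
    if nd.n_rows != fd.n_rows:
        raise RuntimeError("internal error: ND/FD row count mismatch")
    return nd, fd, category_levels


# ---------------------------------------------------------------------------
# Native AdaBoost over depth-1 stumps
# ---------------------------------------------------------------------------

def adaboost_round(w, h_pred, y):
    """One boosting round: weighted error, learner weight, updated weights.

    ``w`` lies on the simplex; predictions/labels are in {0,1} and are mapped
    to +/-1 internally for the exponential reweighting.  eps = 0 clips the
    learner weight at alpha_max = 0.5*log((1-eps_min)/eps_min); eps = 0.5 is
    the alpha = 0 fixed point (weights unchanged).
    """
    w = np.asarray(w, dtype=float)
    h_pred = np.asarray(h_pred)
    y = np.asarray(y)
    miss = (h_pred != y).astype(float)
    eps = float(w @ miss)
    if eps <= 0.0:
        alpha = 0.5 * np.log((1 - _ALPHA_EPS_MIN) / _ALPHA_EPS_MIN)
    else:
        alpha = 0.5 * np.log((1 - eps) / eps)
    h_s = 2.0 * (h_pred == 1) - 1.0
    y_s = 2.0 * (y == 1) - 1.0
    w_next = w * np.exp(-alpha * y_s * h_s)
    w_next = w_next / w_next.sum()
    return eps, float(alpha), w_next


class StumpAdaBoostClassifier(BaseEstimator, ClassifierMixin):
    """Discrete AdaBoost with depth-1 decision stumps.

    Weak learners are single-split CARTs fitted with the current sample
    weights; the learner weight is alpha_t = 0.5*log((1-eps_t)/eps_t) and
    sample weights are renormalized to the simplex each round.  Boosting
    stops when a round's weighted error reaches 0.5 (round discarded) or 0
    (alpha clipped, learner kept).  The ensemble score s(x) = sum_t alpha_t
    h_t(x) (h in {-1,+1}) maps to a probability via the sigmoid.
    """

    def __init__(self, n_estimators: int = 50, learning_rate: float = 1.0, random_state: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("AdaBoost requires both classes present")
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.stumps_ = []  # (feature, threshold, left_label, right_label)
        self.alphas_ = []
        for _ in range(self.n_estimators):
            stump = DecisionTreeClassifier(max_depth=1, random_state=0)
            stump.fit(X, y, sample_weight=w)
            pred = stump.predict(X)
            eps, alpha, w_next = adaboost_round(w, pred, y)
            if eps >= 0.5:
                break  # no better than weighted chance: discard and stop
            self.stumps_.append(_extract_stump(stump))
            self.alphas_.append(self.learning_rate * alpha)
            if eps <= 0.0:
                break  # perfect weak learner; alpha clipped, nothing to reweight
            w = w_next
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "stumps_")
        X = np.asarray(X, dtype=float)
        s = np.zeros(len(X))
        for (feat, thr, left, right), alpha in zip(self.stumps_, self.alphas_):
            if feat < 0:
                lab = np.full(len(X), left)
            else:
                lab = np.where(X[:, feat] <= thr, left, right)
            s += alpha * (2.0 * lab - 1.0)
        return s

    def predict_proba(self, X):
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    # -- JSON persistence (documented native layout) ----------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "stumps_")
        return {
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "random_state": self.random_state,
            "n_features": int(self.n_features_in_),
            "stumps": [
                {"feature": int(f), "threshold": repr(float(t)), "left": int(l), "right": int(r)}
                for f, t, l, r in self.stumps_
            ],
            "alphas": [repr(float(a)) for a in self.alphas_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StumpAdaBoostClassifier":
        obj = cls(d["n_estimators"], d["learning_rate"], d["random_state"])
        obj.stumps_ = [
            (s["feature"], float(s["threshold"]), s["left"], s["right"])
            for s in d["stumps"]
        ]
        obj.alphas_ = [float(a) for a in d["alphas"]]
        obj.classes_ = np.array([0, 1])
        obj.n_features_in_ = d["n_features"]
        return obj


def _extract_stump(tree: DecisionTreeClassifier):
    t = tree.tree_
    classes = tree.classes_
    if t.node_count == 1:
        lab = int(classes[np.argmax(t.value[0])])
        return (-1, 0.0, lab, lab)
    left_lab = int(classes[np.argmax(t.value[t.children_left[0]])])
    right_lab = int(classes[np.argmax(t.value[t.children_right[0]])])
    return (int(t.feature[0]), float(t.threshold[0]), left_lab, right_lab)


# ---------------------------------------------------------------------------
# Slot learner contract
# ---------------------------------------------------------------------------

class SlotLearner:
    """One fitted base-model slot: a kind, a view tag, and a scorer.

    ``probability`` = sigmoid(raw score); learners that natively emit
    probabilities report ``raw_score`` = logit(p).
    """

    def __init__(self, kind: str, view_tag: str, seed: int = 0, slot_index: int = 0, params: dict | None = None):
        self.kind = kind
        self.view_tag = view_tag
        self.seed = seed
        self.slot_index = slot_index
        self.params = params or {}
        self._model = None
        self._encoder = None

    # -- fitting -----------------------------------------------------------
    def fit(self, view: FeatureView, y) -> "SlotLearner":
        if view.tag != self.view_tag:
            raise ValueError(
                f"slot {self.slot_index} ({self.kind}) expects the {self.view_tag} "
                f"view but received {view.tag}"
            )
        if view.frame.shape[1] == 0:
            raise ValueError(
                f"slot {self.slot_index} ({self.kind}): routed {view.tag} view has no columns"
            )
        X = view.matrix
        y = np.asarray(y)
        if self.kind == "xgboost":
            from xgboost import XGBClassifier

            self._model = XGBClassifier(
                n_estimators=100,
                gamma=0.0,
                reg_lambda=1.0,
                tree_method="hist",
                n_jobs=1,
                random_state=self.seed,
                eval_metric="logloss",
                **self.params,
            )
            self._model.fit(X, y)
        elif self.kind == "lightgbm":
            from lightgbm import LGBMClassifier

            self._model = LGBMClassifier(
                n_estimators=100,
                reg_lambda=1.0,
                min_child_samples=5,
                min_split_gain=0.0,
                n_jobs=1,
                random_state=self.seed,
                verbose=-1,
                **self.params,
            )
            # stable column names keep train/predict representations aligned
            self._model.fit(view.frame.astype(float), y)
        elif self.kind == "target_encoded_gbdt":
            from xgboost import XGBClassifier

            fd_as = self.params.get("fd_as", "categorical")
            if fd_as == "categorical":
                self._encoder = OrderedTargetEncoder(
                    a=self.params.get("a", 1.0),
                    prior=self.params.get("prior"),
                    order_seed=self.seed,
                )
                X = self._encoder.fit_transform(view.frame.to_numpy(), y)
            self._model = XGBClassifier(
                n_estimators=self.params.get("n_rounds", 100),
                learning_rate=self.params.get("learning_rate", 0.1),
                max_depth=self.params.get("max_depth", 6),
                reg_lambda=1.0,
                tree_method="hist",
                n_jobs=1,
                random_state=self.seed,
                eval_metric="logloss",
            )
            self._model.fit(X, y)
        elif self.kind == "adaboost":
            self._model = StumpAdaBoostClassifier(
                n_estimators=self.params.get("n_estimators", 50),
                learning_rate=self.params.get("learning_rate", 1.0),
                random_state=self.seed,
            )
            self._model.fit(X, y)
        elif self.kind == "stub":
            self._model = LogisticRegression(max_iter=1000, random_state=self.seed)
            self._model.fit(X, y)
        else:
            raise ValueError(f"unknown slot learner kind {self.kind!r}")
        return self

    # -- scoring -----------------------------------------------------------
    def _check_view(self, view: FeatureView) -> np.ndarray:
        if view.tag != self.view_tag:
            raise ValueError(
                f"view-tag mismatch: slot {self.slot_index} ({self.kind}) is bound "
                f"to {self.view_tag} but was given the {view.tag} view"
            )
        return view.matrix

    def probability(self, view: FeatureView) -> np.ndarray:
        X = self._check_view(view)
        if self.kind == "target_encoded_gbdt" and self._encoder is not None:
            X = self._encoder.transform(view.frame.to_numpy())
        elif self.kind == "lightgbm":
            X = view.frame.astype(float)
        if hasattr(self._model, "predict_proba"):
            p = self._model.predict_proba(X)[:, 1]
        else:  # lightgbm Booster loaded from text
            p = np.asarray(self._model.predict(X))
        return np.clip(p, _EPS_P, 1 - _EPS_P)

    def raw_score(self, view: FeatureView) -> np.ndarray:
        return logit(self.probability(view))

    # -- persistence -------------------------------------------------------
    def save(self, directory: str) -> dict:
        prefix = f"slot_{self.slot_index}_{self.kind}"
        entry = {
            "slot": self.slot_index,
            "kind": self.kind,
            "view": self.view_tag,
            "seed": self.seed,
            "params": self.params,
        }
        if self.kind in ("xgboost",):
            fn = prefix + ".xgb.json"
            self._model.get_booster().save_model(os.path.join(directory, fn))
            entry["state"] = fn
        elif self.kind == "lightgbm":
            fn = prefix + ".lgb.txt"
            with open(os.path.join(directory, fn), "w", encoding="utf-8") as fh:
                fh.write(self._model.booster_.model_to_string())
            entry["state"] = fn
        elif self.kind == "target_encoded_gbdt":
            fn = prefix + ".xgb.json"
            self._model.get_booster().save_model(os.path.join(directory, fn))
            entry["state"] = fn
            if self._encoder is not None:
                efn = prefix + ".encoder.json"
                with open(os.path.join(directory, efn), "w", encoding="utf-8") as fh:
                    json.dump(self._encoder.to_dict(), fh, sort_keys=True)
                entry["encoder"] = efn
        elif self.kind == "adaboost":
            fn = prefix + ".json"
            with open(os.path.join(directory, fn), "w", encoding="utf-8") as fh:
                json.dump(self._model.to_dict(), fh)
            entry["state"] = fn
        elif self.kind == "stub":
            fn = prefix + ".json"
            doc = {
                "coef": self._model.coef_.tolist(),
                "intercept": self._model.intercept_.tolist(),
            }
            with open(os.path.join(directory, fn), "w", encoding="utf-8") as fh:
                json.dump(doc, fh)
            entry["state"] = fn
        return entry

    @classmethod
    def load(cls, directory: str, entry: dict) -> "SlotLearner":
        obj = cls(
            kind=entry["kind"],
            view_tag=entry["view"],
            seed=entry["seed"],
            slot_index=entry["slot"],
            params=entry.get("params", {}),
        )
        path = os.path.join(directory, entry["state"])
        if obj.kind in ("xgboost", "target_encoded_gbdt"):
            from xgboost import XGBClassifier

            obj._model = XGBClassifier()
            obj._model.load_model(path)
            if "encoder" in entry:
                with open(os.path.join(directory, entry["encoder"]), encoding="utf-8") as fh:
                    obj._encoder = OrderedTargetEncoder.from_dict(json.load(fh))
        elif obj.kind == "lightgbm":
            import lightgbm as lgb

            with open(path, encoding="utf-8") as fh:
                obj._model = lgb.Booster(model_str=fh.read())
        elif obj.kind == "adaboost":
            with open(path, encoding="utf-8") as fh:
                obj._model = StumpAdaBoostClassifier.from_dict(json.load(fh))
        elif obj.kind == "stub":
            with open(path, encoding="utf-8") as fh:
                doc = json.load(fh)
            obj._model = LogisticRegression()
            obj._model.coef_ = np.array(doc["coef"])
            obj._model.intercept_ = np.array(doc["intercept"])
            obj._model.classes_ = np.array([0, 1])
        return obj


def make_slot_learner(kind: str, view_tag: str, seed: int, slot_index: int, params: dict | None = None) -> SlotLearner:
    return SlotLearner(kind, view_tag, seed, slot_index, params)


def fit_base_models(
    nd_view: FeatureView,
    fd_view: FeatureView,
    y,
    plan: RoutingPlan = DEFAULT_PLAN,
    seeds: list[int] | None = None,
    slot_params: dict | None = None,
) -> list[SlotLearner]:
    """Fit every slot of the routing plan on its routed view."""
    if nd_view.n_rows != fd_view.n_rows:
        raise RuntimeError("internal error: view row counts differ")
    if len(np.unique(np.asarray(y))) < 2:
        raise ValueError("fitting the base layer requires both classes present")
    seeds = seeds if seeds is not None else list(range(plan.n_slots))
    views = {"ND": nd_view, "FD": fd_view}
    learners = []
    for m, (kind, tag) in enumerate(plan.slots):
        params = (slot_params or {}).get(kind, {})
        learner = make_slot_learner(kind, tag, seeds[m], m, params)
        learner.fit(views[tag], y)
        learners.append(learner)
    return learners


def base_probabilities(
    learners: list[SlotLearner], nd_view: FeatureView, fd_view: FeatureView
) -> np.ndarray:
    """N x M matrix of slot probabilities in plan order, entries in (0, 1)."""
    views = {"ND": nd_view, "FD": fd_view}
    cols = [lrn.probability(views[lrn.view_tag]) for lrn in learners]
    return np.column_stack(cols)
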