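"""Second-layer fusion and the end-to-end FADEL classifier.

The four base-slot probabilities for a row form its meta-feature vector
v = [p1, p2, p3, p4]; a random forest fitted on these vectors fuses them.
The final label is the majority vote of the per-tree argmax predictions
(ties on an even tree count go to the negative class); the continuous score
used for ROC/PR curves is the forest's mean leaf probability of class 1.

``FadelClassifier`` is a scikit-learn-compatible estimator composing the
whole pipeline: supervised discretization fitted on the training rows, view
construction, routed base layer, meta-feature assembly (out-of-fold by
default, to keep the meta-model from learning the base layer's training
optimism; ``meta_mode="direct"`` reproduces the literal in-sample reading),
and the forest meta-model.
"""

from __future__ import annotations

import json
import os

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .base import (
    DEFAULT_PLAN,
    FeatureView,
    RoutingPlan,
    SlotLearner,
    base_probabilities,
    build_views,
    fit_base_models,
)
from .data import FeatureSchema, TabularDataset
from .discretize import CartBinner

__all__ = [
    "assemble_meta_features",
    "fit_meta",
    "vote",
    "FadelClassifier",
    "fit_fadel",
    "predict",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


def assemble_meta_features(
    nd_view: FeatureView,
    fd_view: FeatureView,
    y,
    plan: RoutingPlan = DEFAULT_PLAN,
    seeds: list[int] | None = None,
    mode: str = "out_of_fold",
    k: int = 5,
    fold_seed: int = 0,
    slot_params: dict | None = None,
):
    """Build the N x n_slots meta-feature matrix and the deployed learners.

    direct: learners are fitted on all rows and the meta-features are their
    in-sample probabilities.  out_of_fold: a stratified k-fold is used so row
    i's vector comes from learners that never saw fold(i); the final learners
    are then refitted on all rows for deployment.
    """
    y = np.asarray(y)
    if mode == "direct":
        learners = fit_base_models(nd_view, fd_view, y, plan, seeds, slot_params)
        return base_probabilities(learners, nd_view, fd_view), learners
    if mode != "out_of_fold":
        raise ValueError(f"unknown meta-feature mode {mode!r}")
    if k < 2:
        raise ValueError("out_of_fold requires k >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"out_of_fold with k={k} needs at least {k} members per class; "
            f"class counts are {counts.tolist()}"
        )
    meta = np.empty((len(y), plan.n_slots))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    for tr, te in skf.split(np.zeros(len(y)), y):
        nd_tr = FeatureView("ND", nd_view.frame.iloc[tr])
        fd_tr = FeatureView("FD", fd_view.frame.iloc[tr])
        fold_learners = fit_base_models(nd_tr, fd_tr, y[tr], plan, seeds, slot_params)
        nd_te = FeatureView("ND", nd_view.frame.iloc[te])
        fd_te = FeatureView("FD", fd_view.frame.iloc[te])
        meta[te] = base_probabilities(fold_learners, nd_te, fd_te)
    final = fit_base_models(nd_view, fd_view, y, plan, seeds, slot_params)
    return meta, final


def fit_meta(meta_features, y, n_trees: int = 100, seed: int = 0) -> RandomForestClassifier:
    """Fit the random-forest meta-model on the probability vectors.

    Trees are grown on bootstrap resamples with random feature subsetting
    over the meta columns; leaves store class-frequency pairs.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("meta-model fitting requires both classes present")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(np.asarray(meta_features, dtype=float), y)
    return forest


def vote(forest: RandomForestClassifier, v) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over the forest's per-tree argmax predictions.

    Returns ``(labels, scores)``; a label is 1 only when strictly more than
    half the trees vote 1 (an exact tie on an even tree count resolves to the
    negative class).  The score is the forest's mean leaf probability of the
    positive class — a continuous companion to the discrete vote, suitable
    for ROC/PR curves.
    """
    V = np.atleast_2d(np.asarray(v, dtype=float))
    tree_votes = np.stack([t.predict(V) for t in forest.estimators_])
    n_pos = (tree_votes == 1).sum(axis=0)
    labels = (2 * n_pos > len(forest.estimators_)).astype(int)
    scores = forest.predict_proba(V)[:, 1]
    return labels, scores


def _derive_seeds(random_state: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(random_state)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


class FadelClassifier(BaseEstimator, ClassifierMixin):
    """Feature-type-aware stacking classifier for imbalanced binary labels.

    Continuous features are discretized by per-feature supervised CART
    thresholding; raw and discretized views are routed to type-compatible
    base learners (gradient boosting on the raw view, ordered-target-encoded
    boosting and stump AdaBoost on the interval view); a random forest fuses
    the four base probabilities and predicts by majority vote.

    Parameters
    ----------
    disc_max_depth, disc_max_leaf_nodes, disc_min_samples_leaf,
    disc_min_samples_split : int
        CART constraints for the per-feature discretizers (defaults give at
        most min(2**3, 8) = 8 intervals per feature).
    plan : RoutingPlan or None
        Base-slot layout; None uses the default four-slot plan.
    meta_mode : {"out_of_fold", "direct"}
        How base probabilities for meta-model training are produced.
    n_folds : int
        Folds for out_of_fold meta features.
    n_meta_trees : int
        Trees in the random-forest meta-model.
    te_a, te_prior : float, float or None
        Target-encoding smoothing and prior (None = training prevalence).
    fd_as : {"categorical", "ordinal"}
        Whether the target-encoded slot consumes interval indices as
        categorical levels (encoded) or ordinal integers (raw).
    categorical_features : list of str, optional
        Columns passed through to both views as categorical codes.
    discretize_features : list of str, optional
        Continuous columns to discretize; None flags all continuous columns.
    random_state : int
        Single seed from which all component seeds are derived.

    Attributes
    ----------
    binner_ : CartBinner
        Fitted per-feature discretizers.
    base_learners_ : list of SlotLearner
    meta_forest_ : RandomForestClassifier
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        disc_max_depth: int = 3,
        disc_max_leaf_nodes: int = 8,
        disc_min_samples_leaf: int = 5,
        disc_min_samples_split: int = 2,
        plan: RoutingPlan | None = None,
        meta_mode: str = "out_of_fold",
        n_folds: int = 5,
        n_meta_trees: int = 100,
        te_a: float = 1.0,
        te_prior: float | None = None,
        fd_as: str = "categorical",
        ada_n_estimators: int = 50,
        ada_learning_rate: float = 1.0,
        categorical_features: list | None = None,
        discretize_features: list | None = None,
        random_state: int = 0,
    ):
        self.disc_max_depth = disc_max_depth
        self.disc_max_leaf_nodes = disc_max_leaf_nodes
        self.disc_min_samples_leaf = disc_min_samples_leaf
        self.disc_min_samples_split = disc_min_samples_split
        self.plan = plan
        self.meta_mode = meta_mode
        self.n_folds = n_folds
        self.n_meta_trees = n_meta_trees
        self.te_a = te_a
        self.te_prior = te_prior
        self.fd_as = fd_as
        self.ada_n_estimators = ada_n_estimators
        self.ada_learning_rate = ada_learning_rate
        self.categorical_features = categorical_features
        self.discretize_features = discretize_features
        self.random_state = random_state

    # -- dataset plumbing --------------------------------------------------
    def _as_dataset(self, X, y=None) -> TabularDataset:
        if isinstance(X, TabularDataset):
            return X
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        cats = set(map(str, self.categorical_features or []))
        flagged = (
            None
            if self.discretize_features is None
            else set(map(str, self.discretize_features))
        )
        schema = []
        for c in X.columns:
            name = str(c)
            if name in cats or not pd.api.types.is_numeric_dtype(X[c]):
                schema.append(FeatureSchema(name, "categorical", False))
            else:
                disc = True if flagged is None else (name in flagged)
                schema.append(FeatureSchema(name, "continuous", disc))
        yy = np.zeros(len(X), dtype=int) if y is None else np.asarray(y)
        return TabularDataset(X=X.reset_index(drop=True), y=yy, schema=schema)

    def _slot_params(self) -> dict:
        return {
            "target_encoded_gbdt": {
                "a": self.te_a,
                "prior": self.te_prior,
                "fd_as": self.fd_as,
            },
            "adaboost": {
                "n_estimators": self.ada_n_estimators,
                "learning_rate": self.ada_learning_rate,
            },
        }

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        ds = self._as_dataset(X, y)
        y_arr = ds.y
        if len(np.unique(y_arr)) < 2:
            raise ValueError("fit requires both classes present")
        flagged = ds.flagged_features
        if not flagged:
            raise ValueError(
                "at least one continuous feature must be flagged for discretization "
                "(the FD slots are otherwise unroutable)"
            )
        plan = self.plan or DEFAULT_PLAN
        seeds = _derive_seeds(self.random_state, plan.n_slots + 2)
        slot_seeds, fold_seed, meta_seed = seeds[:-2], seeds[-2], seeds[-1]

        self.binner_ = CartBinner(
            max_depth=self.disc_max_depth,
            max_leaf_nodes=self.disc_max_leaf_nodes,
            min_samples_leaf=self.disc_min_samples_leaf,
            min_samples_split=self.disc_min_samples_split,
        )
        self.binner_.fit(ds.X[flagged], y_arr)
        self.discretizers_ = {
            d.feature_name: d for d in self.binner_.discretizers_
        }
        nd, fd, self.category_levels_ = build_views(ds, self.discretizers_)
        meta, self.base_learners_ = assemble_meta_features(
            nd,
            fd,
            y_arr,
            plan,
            slot_seeds,
            mode=self.meta_mode,
            k=self.n_folds,
            fold_seed=fold_seed,
            slot_params=self._slot_params(),
        )
        self.meta_forest_ = fit_meta(meta, y_arr, self.n_meta_trees, meta_seed)
        self.plan_ = plan
        self.meta_features_ = meta
        self.classes_ = np.array([0, 1])
        self.prior_ = float(y_arr.mean())
        self.feature_names_in_ = np.asarray([s.name for s in ds.schema], dtype=object)
        self.schema_ = list(ds.schema)
        self.n_features_in_ = len(self.schema_)
        return self

    def _views(self, X):
        check_is_fitted(self, "meta_forest_")
        ds = self._as_dataset(X)
        names = [s.name for s in self.schema_]
        missing = set(names) - set(str(c) for c in ds.X.columns)
        if missing:
            raise ValueError(f"input is missing model columns: {sorted(missing)}")
        ds = TabularDataset(
            X=ds.X[names].reset_index(drop=True), y=ds.y, schema=list(self.schema_)
        )
        nd, fd, _ = build_views(ds, self.discretizers_, self.category_levels_)
        return nd, fd

    def base_probabilities_of(self, X) -> np.ndarray:
        """The N x n_slots matrix of base-slot probabilities for new rows."""
        nd, fd = self._views(X)
        return base_probabilities(self.base_learners_, nd, fd)

    def predict_proba(self, X) -> np.ndarray:
        meta = self.base_probabilities_of(X)
        return self.meta_forest_.predict_proba(meta)

    def decision_scores(self, X) -> np.ndarray:
        """Continuous score in [0, 1]: the forest's mean leaf q(y=1)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        meta = self.base_probabilities_of(X)
        labels, _ = vote(self.meta_forest_, meta)
        return labels

    def predict_with_scores(self, X) -> tuple[np.ndarray, np.ndarray]:
        meta = self.base_probabilities_of(X)
        return vote(self.meta_forest_, meta)


# ---------------------------------------------------------------------------
# Functional wrappers and the model archive
# ---------------------------------------------------------------------------

def fit_fadel(ds: TabularDataset, config: dict | None = None) -> FadelClassifier:
    """Fit the full pipeline on a :class:`TabularDataset`."""
    model = FadelClassifier(**(config or {}))
    return model.fit(ds, ds.y)


def predict(model: FadelClassifier, ds) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (label, continuous score) for new rows."""
    return model.predict_with_scores(ds)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_model(model: FadelClassifier, directory: str) -> None:
    """Persist a fitted model as a directory archive.

    ``manifest.json`` records the format version, routing plan, configuration
    and schema; discretizers and the native learners are JSON; the two GBDT
    slots use their libraries' own text formats; the meta forest is a joblib
    blob.
    """
    check_is_fitted(model, "meta_forest_")
    os.makedirs(directory, exist_ok=True)
    slot_entries = [lrn.save(directory) for lrn in model.base_learners_]
    model.binner_.save(os.path.join(directory, "discretizers.json"))
    joblib.dump(model.meta_forest_, os.path.join(directory, "meta_forest.joblib"))
    params = model.get_params()
    params["plan"] = None  # plan recorded explicitly below
    manifest = {
        "format_version": FORMAT_VERSION,
        "plan": [list(s) for s in model.plan_.slots],
        "config": params,
        "schema": [
            {"name": s.name, "kind": s.kind, "discretize": s.discretize}
            for s in model.schema_
        ],
        "category_levels": model.category_levels_,
        "prior": model.prior_,
        "slots": slot_entries,
        "meta_forest": "meta_forest.joblib",
        "discretizers": "discretizers.json",
    }
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_model(directory: str) -> FadelClassifier:
    with open(os.path.join(directory, "manifest.json"), encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {manifest.get('format_version')!r}; "
            f"this build reads version {FORMAT_VERSION}"
        )
    config = dict(manifest["config"])
    plan = RoutingPlan(tuple(tuple(s) for s in manifest["plan"]))
    config["plan"] = None
    model = FadelClassifier(**config)
    model.plan_ = plan
    model.binner_ = CartBinner.load(os.path.join(directory, manifest["discretizers"]))
    model.discretizers_ = {d.feature_name: d for d in model.binner_.discretizers_}
    model.base_learners_ = [
        SlotLearner.load(directory, entry) for entry in manifest["slots"]
    ]
    model.meta_forest_ = joblib.load(os.path.join(directory, manifest["meta_forest"]))
    model.schema_ = [
        FeatureSchema(s["name"], s["kind"], s["discretize"]) for s in manifest["schema"]
    ]
    model.category_levels_ = manifest["category_levels"]
    model.prior_ = manifest["prior"]
    model.classes_ = np.array([0, 1])
    model.feature_names_in_ = np.asarray([s.name for s in model.schema_], dtype=object)
    model.n_features_in_ = len(model.schema_)
    return model
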