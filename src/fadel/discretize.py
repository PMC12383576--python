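"""Supervised CART-threshold discretization of continuous features.

Each continuous feature j is discretized by growing a small CART classifier on
the (x_j, y) pairs and harvesting the split values at its internal nodes.  The
sorted, deduplicated split values theta_j(1) < ... < theta_j(K-1) partition the
real line into K right-closed intervals

    I_j(k) = { x : theta_j(k-1) < x <= theta_j(k) },   k = 1..K,

with virtual boundaries theta_j(0) = -inf and theta_j(K) = +inf.  A value maps
to the 1-based index of the interval containing it.  With maximum tree depth D
and leaf budget L the interval count obeys K <= min(2^D, L).

Unsupervised equal-width and equal-frequency binning are provided as baselines
producing the same threshold representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .data import TabularDataset

__all__ = [
    "DiscretizerConfig",
    "FeatureDiscretizer",
    "CartBinner",
    "fit_feature_discretizer",
    "fit_unsupervised_bins",
    "assign_interval",
    "interval_index_sum_form",
    "transform_dataset",
]


@dataclass(frozen=True)
class DiscretizerConfig:
    """CART growth constraints for one feature (defaults per the reference
    configuration: depth 3, at most 8 leaves, Gini impurity)."""

    max_depth: int = 3
    max_leaf_nodes: int = 8
    min_samples_leaf: int = 5
    min_samples_split: int = 2
    criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.max_leaf_nodes < 2:
            raise ValueError("max_leaf_nodes must be >= 2")
        if self.criterion != "gini":
            raise ValueError("split criterion is fixed to Gini impurity")

    @property
    def max_intervals(self) -> int:
        """Upper bound K <= min(2^D, L)."""
        return min(2 ** self.max_depth, self.max_leaf_nodes)


@dataclass
class FeatureDiscretizer:
    """Ordered threshold vector and interval mapper for one feature."""

    feature_name: str
    thresholds: np.ndarray
    config: DiscretizerConfig | None = None
    #: the root (first, strongest) CART split value, when fitted from a tree
    first_threshold: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1:
            raise ValueError("thresholds must be a 1-D sequence")
        if not np.all(np.isfinite(t)):
            raise ValueError("thresholds must be finite (the +/-inf bounds are virtual)")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = t

    @property
    def n_intervals(self) -> int:
        return self.thresholds.size + 1

    def assign(self, x) -> np.ndarray:
        """Vectorized interval assignment, 1-based."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(
                f"non-finite value passed to discretizer for {self.feature_name!r}"
            )
        # right-closed intervals: x == theta(k) belongs to interval k
        return np.searchsorted(self.thresholds, x, side="left") + 1

    def to_dict(self) -> dict:
        d = {
            "feature": self.feature_name,
            "thresholds": [repr(float(t)) for t in self.thresholds],
            "n_intervals": self.n_intervals,
        }
        if self.config is not None:
            d["config"] = {
                "max_depth": self.config.max_depth,
                "max_leaf_nodes": self.config.max_leaf_nodes,
                "min_samples_leaf": self.config.min_samples_leaf,
                "min_samples_split": self.config.min_samples_split,
                "criterion": self.config.criterion,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDiscretizer":
        cfg = DiscretizerConfig(**d["config"]) if "config" in d else None
        return cls(
            feature_name=d["feature"],
            thresholds=np.array([float(t) for t in d["thresholds"]]),
            config=cfg,
        )


def fit_feature_discretizer(
    x, y, config: DiscretizerConfig | None = None, feature_name: str = "x"
) -> FeatureDiscretizer:
    """Grow a constrained CART on one feature and extract its split thresholds.

    The tree is grown best-first under the leaf budget (scikit-learn's
    behaviour whenever ``max_leaf_nodes`` is set); split values at internal
    nodes are collected, deduplicated and sorted ascending.  A constant
    feature yields no thresholds (K = 1) rather than an error.
    """
    config = config or DiscretizerConfig()
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"feature {feature_name!r}: supervised discretization needs both classes"
        )
    if np.unique(x).size == 1:
        return FeatureDiscretizer(feature_name, np.array([]), config)
    tree = DecisionTreeClassifier(
        criterion=config.criterion,
        max_depth=config.max_depth,
        max_leaf_nodes=config.max_leaf_nodes,
        min_samples_leaf=config.min_samples_leaf,
        min_samples_split=config.min_samples_split,
        random_state=0,
    )
    tree.fit(x, y)
    internal = tree.tree_.children_left != -1
    thresholds = np.unique(tree.tree_.threshold[internal])
    first = float(tree.tree_.threshold[0]) if internal[0] else None
    return FeatureDiscretizer(feature_name, thresholds, config, first_threshold=first)


def fit_unsupervised_bins(
    x, n_bins: int, mode: str = "equal_width", feature_name: str = "x"
) -> FeatureDiscretizer:
    """Equal-width or equal-frequency binning baseline.

    equal_width: thresholds at min + i*(max-min)/n_bins, i = 1..n_bins-1.
    equal_frequency: thresholds at the i/n_bins empirical quantiles, with
    duplicate quantiles collapsed (K may shrink).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    if mode == "equal_width":
        lo, hi = x.min(), x.max()
        if lo == hi:
            return FeatureDiscretizer(feature_name, np.array([]))
        thresholds = lo + np.arange(1, n_bins) * (hi - lo) / n_bins
    elif mode == "equal_frequency":
        q = np.arange(1, n_bins) / n_bins
        thresholds = np.unique(np.quantile(x, q))
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    thresholds = np.unique(thresholds)
    return FeatureDiscretizer(feature_name, thresholds)


def assign_interval(disc: FeatureDiscretizer, x: float) -> int:
    """Scalar interval index: the unique k with theta(k-1) < x <= theta(k)."""
    if not np.isfinite(x):
        raise ValueError(f"non-finite value {x!r}")
    return int(disc.assign(np.array([x]))[0])


def interval_index_sum_form(thresholds, x: float) -> int:
    """Summation form of the interval index, sum_k k * 1[x in I(k)].

    Equivalent to the scan/`searchsorted` form; kept as a directly readable
    rendering of the indicator decomposition for cross-checking.
    """
    t = np.concatenate(([-np.inf], np.asarray(thresholds, float), [np.inf]))
    k = np.arange(1, len(t))
    ind = (x > t[:-1]) & (x <= t[1:])
    return int((k * ind).sum())


class CartBinner(BaseEstimator, TransformerMixin):
    """Column-wise supervised CART discretizer (scikit-learn transformer).

    Fits one :class:`FeatureDiscretizer` per column of ``X`` and transforms
    values into 1-based interval indices.  Accepts arrays or DataFrames; with
    a DataFrame, column names are preserved in ``discretizers_``.

    Parameters follow the reference configuration: ``max_depth=3``,
    ``max_leaf_nodes=8``, ``min_samples_leaf=5``, ``min_samples_split=2``,
    giving at most ``min(2**3, 8) = 8`` intervals per feature.
    """

    def __init__(
        self,
        max_depth: int = 3,
        max_leaf_nodes: int = 8,
        min_samples_leaf: int = 5,
        min_samples_split: int = 2,
    ):
        self.max_depth = max_depth
        self.max_leaf_nodes = max_leaf_nodes
        self.min_samples_leaf = min_samples_leaf
        self.min_samples_split = min_samples_split

    def _config(self) -> DiscretizerConfig:
        return DiscretizerConfig(
            max_depth=self.max_depth,
            max_leaf_nodes=self.max_leaf_nodes,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
        )

    def fit(self, X, y):
        X = pd.DataFrame(X)
        cfg = self._config()
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        self.discretizers_ = [
            fit_feature_discretizer(X[c].to_numpy(), y, cfg, feature_name=str(c))
            for c in X.columns
        ]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "discretizers_")
        X = pd.DataFrame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        cols = [d.assign(X.iloc[:, j].to_numpy()) for j, d in enumerate(self.discretizers_)]
        if not cols:
            return np.empty((len(X), 0), dtype=np.int64)
        return np.column_stack(cols).astype(np.int64)

    @property
    def n_intervals_(self) -> list[int]:
        check_is_fitted(self, "discretizers_")
        return [d.n_intervals for d in self.discretizers_]

    def save(self, path: str) -> None:
        doc = [d.to_dict() for d in self.discretizers_]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "CartBinner":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        discs = [FeatureDiscretizer.from_dict(d) for d in doc]
        cfg = discs[0].config if discs and discs[0].config else DiscretizerConfig()
        binner = cls(
            max_depth=cfg.max_depth,
            max_leaf_nodes=cfg.max_leaf_nodes,
            min_samples_leaf=cfg.min_samples_leaf,
            min_samples_split=cfg.min_samples_split,
        )
        binner.discretizers_ = discs
        binner.feature_names_in_ = np.asarray([d.feature_name for d in discs], dtype=object)
        binner.n_features_in_ = len(discs)
        return binner


def transform_dataset(
    ds: TabularDataset, discretizers: dict[str, FeatureDiscretizer]
) -> pd.DataFrame:
    """Apply fitted per-feature discretizers to the dataset's flagged columns.

    Returns the discretized view: one integer column per flagged feature,
    every entry in {1..K_j}.  Unflagged columns are excluded (they belong to
    the non-discretized view).
    """
    cols = {}
    for name in ds.flagged_features:
        if name not in discretizers:
            raise KeyError(f"no fitted discretizer for flagged feature {name!r}")
        cols[name] = discretizers[name].assign(ds.X[name].to_numpy())
    return pd.DataFrame(cols, index=ds.X.index, dtype=np.int64)
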