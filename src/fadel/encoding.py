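"""Ordered target encoding of categorical / interval-index columns.

A categorical level is replaced by a smoothed running mean of the label over
the samples of that level seen *before* the current one in a (seeded)
traversal order:

    TE(x_i) = (sum_{k<i, x_k = x_i} y_k + a * p) / (#{k<i : x_k = x_i} + a)

with smoothing ``a`` and prior ``p``.  The strict "preceding samples only"
sum means a sample's own label never leaks into its encoding.  At transform
time (unseen rows) the full training statistics are used; an unseen level
encodes to the prior.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["OrderedTargetEncoder", "target_encode_fit_transform"]


def _encode_column(codes, y, a, p, order):
    codes = np.asarray(codes)
    y = np.asarray(y, dtype=float)
    enc = np.empty(len(codes), dtype=float)
    stats: dict = {}
    for i in order:
        c = codes[i]
        s, n = stats.get(c, (0.0, 0))
        denom = n + a
        enc[i] = (s + a * p) / denom if denom > 0 else p
        stats[c] = (s + y[i], n + 1)
    return enc, stats


def target_encode_fit_transform(
    codes, y, a: float = 1.0, p: float = 0.5, order_seed: int | None = None
):
    """Ordered target encoding of one categorical column.

    ``order_seed=None`` traverses in dataset order; an integer seeds a random
    permutation (ordered-boosting style).  Returns ``(encoded, state)`` where
    ``state`` maps category -> (label sum, count) over all samples.
    """
    if a < 0:
        raise ValueError("smoothing a must be nonnegative")
    codes = np.asarray(codes)
    n = len(codes)
    if order_seed is None:
        order = np.arange(n)
    else:
        order = np.random.default_rng(order_seed).permutation(n)
    return _encode_column(codes, y, a, p, order)


class OrderedTargetEncoder(BaseEstimator, TransformerMixin):
    """Column-wise ordered target encoder (scikit-learn transformer).

    Parameters
    ----------
    a : float
        Smoothing strength (pseudo-count on the prior).
    prior : float or None
        Prior probability ``p``; None uses the training positive prevalence.
    order_seed : int or None
        Seed for the traversal permutation used during ``fit_transform``;
        None traverses in dataset order.  One permutation per fit, shared
        across columns.
    """

    def __init__(self, a: float = 1.0, prior: float | None = None, order_seed: int | None = 0):
        self.a = a
        self.prior = prior
        self.order_seed = order_seed

    def fit(self, X, y):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y, **fit_params):
        X = np.asarray(X)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(y, dtype=float)
        self.prior_ = float(y.mean()) if self.prior is None else float(self.prior)
        if self.a == 0:
            import warnings

            warnings.warn(
                "a=0: first occurrences of a category are 0/0 and encode to the prior",
                RuntimeWarning,
                stacklevel=2,
            )
        n = len(y)
        if self.order_seed is None:
            order = np.arange(n)
        else:
            order = np.random.default_rng(self.order_seed).permutation(n)
        out = np.empty(X.shape, dtype=float)
        self.stats_ = []
        for j in range(X.shape[1]):
            out[:, j], stats = _encode_column(X[:, j], y, self.a, self.prior_, order)
            self.stats_.append(stats)
        self.n_features_in_ = X.shape[1]
        return out

    def transform(self, X):
        check_is_fitted(self, "stats_")
        X = np.asarray(X)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        out = np.empty(X.shape, dtype=float)
        for j in range(X.shape[1]):
            stats = self.stats_[j]
            for i, c in enumerate(X[:, j]):
                s, n = stats.get(c, (0.0, 0))
                denom = n + self.a
                out[i, j] = (s + self.a * self.prior_) / denom if denom > 0 else self.prior_
        return out

    def to_dict(self) -> dict:
        check_is_fitted(self, "stats_")
        return {
            "a": self.a,
            "prior": self.prior_,
            "order_seed": self.order_seed,
            "stats": [
                {str(k): [float(s), int(n)] for k, (s, n) in col.items()}
                for col in self.stats_
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrderedTargetEncoder":
        enc = cls(a=d["a"], prior=d["prior"], order_seed=d["order_seed"])
        enc.prior_ = d["prior"]
        # keys were interval indices / category codes stringified for JSON;
        # restore integer keys where possible
        def _key(k):
            try:
                return int(k)
            except ValueError:
                try:
                    return float(k)
                except ValueError:
                    return k

        enc.stats_ = [
            {_key(k): (v[0], v[1]) for k, v in col.items()} for col in d["stats"]
        ]
        enc.n_features_in_ = len(enc.stats_)
        return enc
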