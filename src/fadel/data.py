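"""Tabular data model, delimited-text I/O and stratified splitting.

The package works on plain delimited text tables (comma or tab separated,
header row mandatory) with one binary label column; the remaining columns are
continuous laboratory-style measurements or categorical flags.  A small schema
records, per feature, whether it is continuous and whether it participates in
supervised discretization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSchema",
    "TabularDataset",
    "SplitResult",
    "load_table",
    "write_table",
    "stratified_split",
    "class_summary",
]


class SchemaError(ValueError):
    """Raised when a table or sidecar violates the schema contract."""


@dataclass(frozen=True)
class FeatureSchema:
    """Per-column metadata.

    Parameters
    ----------
    name : str
        Unique column identifier.
    kind : {"continuous", "categorical"}
    discretize : bool
        Whether the column participates in supervised discretization.
        Only continuous columns may be flagged.
    """

    name: str
    kind: str = "continuous"
    discretize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.discretize and self.kind != "continuous":
            raise SchemaError(
                f"feature {self.name!r}: only continuous columns may be discretized"
            )


@dataclass
class TabularDataset:
    """Feature matrix with per-column schema and binary labels.

    ``X`` is a pandas DataFrame (N rows, d feature columns), ``y`` an integer
    array in {0, 1} with 1 the minority/positive class by convention.
    """

    X: pd.DataFrame
    y: np.ndarray
    schema: list[FeatureSchema] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y):
            raise SchemaError(
                f"row count mismatch: X has {len(self.X)} rows, y has {len(self.y)}"
            )
        bad = set(np.unique(self.y)) - {0, 1}
        if bad:
            raise SchemaError(f"labels must be in {{0,1}}; found {sorted(bad)}")
        if not self.schema:
            self.schema = [
                FeatureSchema(
                    name=str(c),
                    kind="continuous" if pd.api.types.is_numeric_dtype(self.X[c]) else "categorical",
                    discretize=bool(pd.api.types.is_numeric_dtype(self.X[c])),
                )
                for c in self.X.columns
            ]
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        if names != [str(c) for c in self.X.columns]:
            raise SchemaError("schema names do not match X columns (order matters)")

    # -- convenience ------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def flagged_features(self) -> list[str]:
        return [s.name for s in self.schema if s.discretize]

    @property
    def categorical_features(self) -> list[str]:
        return [s.name for s in self.schema if s.kind == "categorical"]

    def subset(self, idx: np.ndarray) -> "TabularDataset":
        return TabularDataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            schema=list(self.schema),
        )


@dataclass
class SplitResult:
    train: TabularDataset
    test: TabularDataset
    seed: int
    train_fraction: float


def _read_sidecar(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def load_table(
    path: str,
    label_column: str = "label",
    positive_label: object = 1,
    schema_overrides: dict | None = None,
    sidecar: str | None = None,
    sep: str | None = None,
) -> TabularDataset:
    """Load a delimited text table into a :class:`TabularDataset`.

    Parameters
    ----------
    path : str
        Delimited text file with a header row (comma by default; tab accepted,
        auto-detected from the header line when ``sep`` is None).
    label_column : str
        Name of the binary label column.
    positive_label : object
        Raw token that maps to class 1; every other distinct token maps to 0.
        Exactly two distinct tokens are allowed.
    schema_overrides : dict, optional
        column name -> "continuous" | "categorical", or a dict
        ``{"kind": ..., "discretize": ...}``.
    sidecar : str, optional
        Path to a JSON schema sidecar mapping column name to
        ``{"kind": ..., "discretize": ...}``.

    Raises
    ------
    SchemaError
        Missing label column, missing values, or non-binary labels.
    """
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise SchemaError(
            f"label column {label_column!r} not found; columns: {list(df.columns)}"
        )
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise SchemaError(
            f"missing value at row {rows[0]}, column {df.columns[cols[0]]!r}; "
            "missing data are rejected at load"
        )

    raw = df[label_column]
    tokens = pd.unique(raw)
    y = (raw == positive_label).to_numpy()
    if not y.any() and str(positive_label) in raw.astype(str).values:
        # tolerate string/number mismatch from text round trips
        y = (raw.astype(str) == str(positive_label)).to_numpy()
    if len(tokens) > 2:
        raise SchemaError(
            f"label column holds {len(tokens)} distinct tokens; expected at most 2"
        )
    X = df.drop(columns=[label_column])

    overrides: dict[str, dict] = {}
    if sidecar is not None:
        for name, entry in _read_sidecar(sidecar).items():
            overrides[name] = dict(entry)
    if schema_overrides:
        for name, entry in schema_overrides.items():
            if isinstance(entry, str):
                entry = {"kind": entry}
            overrides.setdefault(name, {}).update(entry)

    schema = []
    for c in X.columns:
        numeric = pd.api.types.is_numeric_dtype(X[c])
        if not numeric:
            # continuous columns must parse as numbers
            try:
                X[c] = pd.to_numeric(X[c])
                numeric = True
            except (ValueError, TypeError):
                numeric = False
        kind = "continuous" if numeric else "categorical"
        disc = numeric
        ov = overrides.get(str(c), {})
        kind = ov.get("kind", kind)
        if kind == "continuous" and not numeric:
            bad = X[c][pd.to_numeric(X[c], errors="coerce").isna()]
            raise SchemaError(
                f"non-numeric value {bad.iloc[0]!r} in continuous column {c!r} "
                f"(row {bad.index[0]})"
            )
        disc = bool(ov.get("discretize", disc and kind == "continuous"))
        if kind == "categorical":
            disc = False
            X[c] = X[c].astype(str)
        schema.append(FeatureSchema(name=str(c), kind=kind, discretize=disc))
    return TabularDataset(X=X, y=y.astype(np.int64), schema=schema)


def write_table(ds: TabularDataset, path: str, label_column: str = "label", sep: str = ",") -> None:
    """Write a dataset back to delimited text (floats via repr round-trip)."""
    df = ds.X.copy()
    df[label_column] = ds.y
    df.to_csv(path, sep=sep, index=False, float_format=None)


def write_sidecar(ds: TabularDataset, path: str) -> None:
    doc = {
        s.name: {"kind": s.kind, "discretize": s.discretize} for s in ds.schema
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _allocate_train_counts(counts: np.ndarray, fraction: float) -> np.ndarray:
    """Largest-fractional-part allocation of train slots across classes.

    Guarantees each class's train count is within +/-1 of
    ``round(count * fraction)`` and totals are consistent.
    """
    exact = counts * fraction
    base = np.floor(exact).astype(int)
    total = int(np.floor(counts.sum() * fraction + 0.5))
    leftover = total - base.sum()
    frac = exact - base
    # ties broken by class index (stable sort on descending fractional part)
    order = np.argsort(-frac, kind="stable")
    alloc = base.copy()
    for j in range(int(leftover)):
        alloc[order[j % len(order)]] += 1
    return np.minimum(alloc, counts)


def stratified_split(
    ds: TabularDataset, train_fraction: float = 0.8, seed: int = 0
) -> SplitResult:
    """Deterministic stratified train/test split.

    Per-class train counts follow the largest-fractional-part rule, so each
    class's allocation is within one row of ``round(class_count * fraction)``.
    """
    if not (0 < train_fraction <= 1):
        raise ValueError(f"train_fraction must be in (0, 1]; got {train_fraction}")
    classes, counts = np.unique(ds.y, return_counts=True)
    if len(classes) < 2 and train_fraction < 1.0:
        raise ValueError("stratified split requires both classes present")
    rng = np.random.default_rng(seed)
    alloc = _allocate_train_counts(counts.astype(float), train_fraction)
    train_idx, test_idx = [], []
    for cls, n_train in zip(classes, alloc):
        n_train = int(n_train)
        members = np.flatnonzero(ds.y == cls)
        perm = rng.permutation(members)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], int)
    return SplitResult(
        train=ds.subset(train_idx),
        test=ds.subset(test_idx),
        seed=seed,
        train_fraction=train_fraction,
    )


def class_summary(ds: TabularDataset) -> tuple[int, int, float]:
    """Return ``(n_neg, n_pos, positive_prevalence)``.

    Prevalence is ``nan`` for an empty dataset.
    """
    n_pos = int((ds.y == 1).sum())
    n_neg = int((ds.y == 0).sum())
    total = n_pos + n_neg
    prev = n_pos / total if total else float("nan")
    return n_neg, n_pos, prev
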