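"""Seeded generator of imbalanced, heterogeneous, skewed tabular datasets.

Emulates the statistical structure of rare-disease laboratory panels: a few
percent positive prevalence, heavily right-skewed lab markers (lognormal /
gamma families with multiplicative class shifts), near-normal hematology
measurements with sub-SD additive shifts, count-like and binary features.
Positives are assigned by exact count (``round(n * prevalence)``), not
per-row coin flips, so prevalence carries no sampling noise; one seed governs
label placement and every feature draw through a stream-splitting scheme
(labels use the first child stream, feature j uses child j+1), so adding a
feature never perturbs the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import FeatureSchema, TabularDataset

__all__ = [
    "FeatureSpec",
    "ScenarioConfig",
    "generate",
    "make_scenario",
    "known_threshold_dataset",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("separable", "clinical_like", "null", "threshold_step")


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic feature: a distribution family, its negative-class
    parameters, and the shift applied to the positive class.

    families: lognormal(mu, sigma) — log-scale location/scale; gamma(shape,
    scale); normal(mu, sd); poisson_like(lam); bernoulli(p).  A
    multiplicative effect scales the draw (equivalently shifts a lognormal's
    log-location); an additive effect shifts it (for bernoulli it shifts the
    event rate, clipped to [0, 1]).
    """

    name: str
    family: str
    params: tuple
    class_effect: float = 0.0
    effect_kind: str = "additive"
    flag: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma", "normal", "poisson_like", "bernoulli"):
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.effect_kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")

    def draw(self, rng: np.random.Generator, n: int, positive: bool) -> np.ndarray:
        p = self.params
        eff = self.class_effect if positive else (0.0 if self.effect_kind == "additive" else 1.0)
        if self.family == "lognormal":
            mu, sigma = p
            x = rng.lognormal(mu, sigma, n)
            return x * eff if self.effect_kind == "multiplicative" else x + eff
        if self.family == "gamma":
            shape, scale = p
            x = rng.gamma(shape, scale, n)
            return x * eff if self.effect_kind == "multiplicative" else x + eff
        if self.family == "normal":
            mu, sd = p
            x = rng.normal(mu, sd, n)
            return x * eff if self.effect_kind == "multiplicative" else x + eff
        if self.family == "poisson_like":
            (lam,) = p
            lam_eff = lam * eff if self.effect_kind == "multiplicative" else lam + eff
            return rng.poisson(max(lam_eff, 0.0), n).astype(float)
        # bernoulli
        (rate,) = p
        r = rate * eff if self.effect_kind == "multiplicative" else rate + eff
        return (rng.random(n) < np.clip(r, 0.0, 1.0)).astype(float)


@dataclass
class ScenarioConfig:
    n: int
    prevalence: float
    features: list = field(default_factory=list)
    seed: int = 0
    name: str = "clinical_like"

    def __post_init__(self) -> None:
        if not (0 < self.prevalence <= 0.5):
            raise ValueError(
                f"prevalence must be in (0, 0.5]; got {self.prevalence}"
            )
        if self.n < 20:
            raise ValueError("n must be >= 20")


def generate(config: ScenarioConfig) -> TabularDataset:
    """Draw a dataset with exactly ``round(n * prevalence)`` positives.

    The ``threshold_step`` scenario delegates to
    :func:`known_threshold_dataset` (its labels are Bernoulli in x by
    construction, so the exact-count rule does not apply there).
    """
    if config.name == "threshold_step":
        c, p_low, p_high = (
            config.features[0].params if config.features else (0.5, 0.01, 0.9)
        )
        return known_threshold_dataset(c, config.n, p_low, p_high, config.seed)
    n_pos = int(round(config.n * config.prevalence))
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.features) + 1)
    label_rng = np.random.default_rng(children[0])
    y = np.zeros(config.n, dtype=np.int64)
    y[label_rng.permutation(config.n)[:n_pos]] = 1
    pos = y == 1

    cols = {}
    schema = []
    for j, spec in enumerate(config.features):
        rng = np.random.default_rng(children[j + 1])
        # draw both class-conditional streams in a fixed order so the layout
        # of y does not change the per-feature stream consumption pattern
        x_neg = spec.draw(rng, config.n - n_pos, positive=False)
        x_pos = spec.draw(rng, n_pos, positive=True)
        x = np.empty(config.n)
        x[~pos] = x_neg
        x[pos] = x_pos
        cols[spec.name] = x
        kind = "categorical" if spec.family == "bernoulli" and not spec.flag else "continuous"
        schema.append(
            FeatureSchema(spec.name, "continuous", spec.flag)
            if kind == "continuous"
            else FeatureSchema(spec.name, "categorical", False)
        )
    X = pd.DataFrame(cols)
    return TabularDataset(X=X, y=y, schema=schema)


def known_threshold_dataset(
    c: float, n: int, p_low: float, p_high: float, seed: int = 0
) -> TabularDataset:
    """Single uniform feature with a step in P(y=1) at x = c.

    x ~ U[0, 1]; P(y=1) = p_low for x <= c and p_high for x > c, drawn as
    exact Bernoulli variates.  Used to check that supervised discretization
    recovers the cut point (recovery is unreliable below a few hundred rows).
    """
    if not (p_low < p_high):
        raise ValueError("p_low must be < p_high")
    if not (0 < c < 1):
        raise ValueError("c must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.random(n)
    p = np.where(x <= c, p_low, p_high)
    y = (rng.random(n) < p).astype(np.int64)
    X = pd.DataFrame({"x": x})
    return TabularDataset(X=X, y=y, schema=[FeatureSchema("x", "continuous", True)])


# ---------------------------------------------------------------------------
# Canonical scenario panels
# ---------------------------------------------------------------------------

def _clinical_panel() -> list[FeatureSpec]:
    # 3 right-skewed "lab" markers with multiplicative positive-class shifts,
    # 4 near-normal "hematology" measurements with sub-SD additive shifts,
    # 1 binary urine flag with an elevated positive-class rate, 1 pure noise.
    return [
        FeatureSpec("crp_like", "lognormal", (3.0, 1.0), 12.0, "multiplicative"),
        FeatureSpec("alt_like", "lognormal", (3.4, 1.2), 7.0, "multiplicative"),
        FeatureSpec("ast_like", "lognormal", (3.8, 1.5), 4.0, "multiplicative"),
        FeatureSpec("wbc_like", "normal", (10.8, 5.9), 11.8, "additive"),
        FeatureSpec("hgb_like", "normal", (12.0, 1.8), -2.7, "additive"),
        FeatureSpec("plt_like", "normal", (294.0, 125.0), 187.5, "additive"),
        FeatureSpec("hct_like", "normal", (35.6, 4.9), -5.9, "additive"),
        FeatureSpec("urine_flag", "bernoulli", (0.07,), 0.78, "additive"),
        FeatureSpec("noise", "normal", (0.0, 1.0), 0.0, "additive"),
    ]


def make_scenario(
    name: str, n: int = 5000, prevalence: float = 0.02, seed: int = 0
) -> ScenarioConfig:
    """Build one of the canonical scenarios.

    separable: two features with effects so large the classes barely overlap.
    clinical_like: the default lab/hematology/urine panel.
    null: the same panel with every class effect removed.
    threshold_step: one uniform feature with a step in P(y=1) at 0.5.
    """
    if name == "separable":
        features = [
            FeatureSpec("marker", "lognormal", (3.0, 0.5), 50.0, "multiplicative"),
            FeatureSpec("score", "normal", (0.0, 1.0), 10.0, "additive"),
        ]
    elif name == "clinical_like":
        features = _clinical_panel()
    elif name == "null":
        features = [
            replace(f, class_effect=0.0 if f.effect_kind == "additive" else 1.0)
            for f in _clinical_panel()
        ]
    elif name == "threshold_step":
        features = [FeatureSpec("x", "normal", (0.5, 0.01, 0.9), 0.0, "additive")]
        # params carry (c, p_low, p_high); family token unused on this path
        return ScenarioConfig(n=n, prevalence=prevalence, features=features, seed=seed, name=name)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return ScenarioConfig(n=n, prevalence=prevalence, features=features, seed=seed, name=name)
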