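import numpy as np
import pandas as pd
import pytest

from fadel import FeatureSchema, TabularDataset, generate, make_scenario


@pytest.fixture(scope="session")
def separable_ds() -> TabularDataset:
    """Small, effectively separable imbalanced dataset."""
    return generate(make_scenario("separable", n=400, prevalence=0.1, seed=7))


@pytest.fixture(scope="session")
def clinical_ds() -> TabularDataset:
    return generate(make_scenario("clinical_like", n=2000, prevalence=0.05, seed=11))


@pytest.fixture()
def tiny_ds() -> TabularDataset:
    X = pd.DataFrame({"crp": [1.0, 2.0, 3.0, 4.0], "flag": ["a", "b", "a", "b"]})
    y = np.array([0, 0, 1, 1])
    schema = [
        FeatureSchema("crp", "continuous", True),
        FeatureSchema("flag", "categorical", False),
    ]
    return TabularDataset(X=X, y=y, schema=schema)
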