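import numpy as np
import pandas as pd
import pytest

from pfasorption import CompoundRegistry, PSSMConfig


@pytest.fixture(scope="session")
def registry() -> CompoundRegistry:
    return CompoundRegistry.bundled()


@pytest.fixture(scope="session")
def fast_config() -> PSSMConfig:
    """Reduced ensemble sizes for unit tests; defaults are exercised in the
    acceptance tier."""
    return PSSMConfig(
        rf_n_estimators=100,
        et_n_estimators=100,
        gb_n_estimators=150,
        mlp_max_iter=1000,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def linear_toy_model():
    """Deterministic 9-feature linear model f(x) = w . x + 1 as a predictor."""
    weights = np.array([0.5, -1.0, 2.0, 0.0, 0.25, -0.75, 1.5, 0.0, -0.5])

    def predict(df: pd.DataFrame) -> np.ndarray:
        return np.asarray(df, dtype=float) @ weights + 1.0

    predict.weights = weights
    return predict
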