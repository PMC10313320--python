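import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lddm import GainMatrix, ModelParams  # noqa: E402


@pytest.fixture
def omega2() -> GainMatrix:
    return GainMatrix(2)


@pytest.fixture
def wta_params() -> ModelParams:
    """The phase-plane example preset: strong recurrence, gated WTA."""
    return ModelParams(alpha=15.0, beta=0.9, sigma=0.0)


@pytest.fixture
def value_params() -> ModelParams:
    """Normalized value-coding preset (disinhibition silent)."""
    return ModelParams(alpha=15.0, beta=0.0, B_R=70.0, sigma=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230601)
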