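"""Shared fixtures: small simulated instances, all generated at test time."""

import numpy as np
import pytest

from bvsreg.model import ChainState, ModelData, Priors


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def small_data(rng):
    """n=60, p=4 instance with one clear signal SNP."""
    n, p = 60, 4
    X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    beta = np.array([0.0, 0.5, 0.0, 0.0])
    y = X @ beta + rng.normal(0, 1.0, n)
    return ModelData(y=y - y.mean(), X=X)


def make_state(data: ModelData, priors: Priors | None = None) -> ChainState:
    priors = (priors or Priors()).resolved(data.y)
    return ChainState.initial(data, priors)
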