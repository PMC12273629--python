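import numpy as np
import pandas as pd
import pytest

from blastabc import (
    DEFAULT_BASE_PARAMS,
    DEFAULT_CHIMERA_PARAMS,
    BaseParams,
    CountDataset,
)


@pytest.fixture
def base_params() -> BaseParams:
    return DEFAULT_BASE_PARAMS


@pytest.fixture
def chimera_params():
    return DEFAULT_CHIMERA_PARAMS


@pytest.fixture
def growth_only_params() -> BaseParams:
    """Pure exponential growth: doubling time 12 h, no transitions."""
    return BaseParams(alpha=np.log(2) / 12, beta=0.0, rho=0.35, zeta=0.0, l=0, eta=0.0, m=0)


@pytest.fixture
def tiny_dataset() -> CountDataset:
    frame = pd.DataFrame(
        {
            "embryo_id": ["a", "b"],
            "condition": ["non-injected"] * 2,
            "T": [90, 95],
            "C": [1, 0],
            "P": [25, 28],
            "E": [22, 24],
        }
    )
    return CountDataset(frame)
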