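import numpy as np
import pytest

from tprbind.itc import SequentialBindingParams

# published global-fit values used as ground truth throughout the suite
TABLE_K1 = 0.1317  # uM^-1
TABLE_K2 = 0.1315  # uM^-1
TABLE_DH1 = -18.756  # kcal/mol
TABLE_DH2 = 0.952  # kcal/mol


@pytest.fixture
def table_params() -> SequentialBindingParams:
    return SequentialBindingParams(TABLE_K1, TABLE_K2, TABLE_DH1, TABLE_DH2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
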