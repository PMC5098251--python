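import numpy as np
import pytest

import besdsim as b


@pytest.fixture(scope="session")
def parent():
    return b.synthetic_parent()


@pytest.fixture(scope="session")
def landscape():
    return b.default_landscape()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


#: the serine-lineage (Clade 1) consensus mutation strings
R4AS_SET = frozenset(
    ["VH S25P", "VH V102N", "VH G104D", "VL I28T", "VL Y50S", "VL F55L",
     "VL K95aE"]
)

#: the histidine-lineage (Clade 2) consensus mutation strings
R4AH_SET = frozenset(["VH G8S", "VH L20I", "VH S25P", "VL Y50H"])


@pytest.fixture(scope="session")
def r4as_set():
    return R4AS_SET


@pytest.fixture(scope="session")
def r4ah_set():
    return R4AH_SET
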