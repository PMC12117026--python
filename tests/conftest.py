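import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scatpol import (FusionConfig, compute_pli_maps, compute_sli_maps,
                     make_phantom, simulate_comsli_stack, simulate_pli_stack)

#: peak-prominence detection threshold used for noiseless phantom analyses
#: (well above the steep-fiber low-contrast modulation, well below real peaks)
PHANTOM_PROMINENCE = 10.0


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom("vervet-like", shape=(64, 64), seed=0)


@pytest.fixture(scope="session")
def pli_stack64(phantom64):
    return simulate_pli_stack(phantom64)


@pytest.fixture(scope="session")
def comsli_stack64(phantom64):
    return simulate_comsli_stack(phantom64)


@pytest.fixture(scope="session")
def pli_maps64(pli_stack64):
    return compute_pli_maps(pli_stack64)


@pytest.fixture(scope="session")
def sli_maps64(comsli_stack64):
    return compute_sli_maps(comsli_stack64, prominence_threshold=PHANTOM_PROMINENCE)


@pytest.fixture(scope="session")
def human_cfg():
    return FusionConfig.preset("human")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
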