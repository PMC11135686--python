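import numpy as np
import pytest

from tgfsmad.pathway_model import default_params, presimulation_steady_state, simulate

FAST_RTOL = 1e-6


@pytest.fixture(scope="session")
def preset():
    return default_params("hacat_like")


@pytest.fixture(scope="session")
def preset_tc(preset):
    """Default 100 pM stimulation over 8 h, 1 min output grid."""
    t = np.arange(0.0, 481.0, 1.0)
    return simulate(preset, 0.1, t)


@pytest.fixture(scope="session")
def preset_ss(preset):
    return presimulation_steady_state(preset)
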