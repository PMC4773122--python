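import numpy as np
import pytest

from dwiphantom.compartments import TissueModelSet, pulse_for_b
from dwiphantom.relaxometry import SequenceTiming, TissueMRParams
from dwiphantom.substrate import SubstrateRecipe, generate_numerical_brain

DELTA_S = 12.9e-3
BIG_DELTA_S = 21.8e-3


@pytest.fixture(scope="session")
def models():
    return TissueModelSet.default()


@pytest.fixture(scope="session")
def pulse_b1000():
    return pulse_for_b(1000.0, DELTA_S, BIG_DELTA_S)


@pytest.fixture(scope="session")
def mrparams_3t():
    return TissueMRParams.preset("3T")


@pytest.fixture(scope="session")
def timing_3t():
    return SequenceTiming(te_ms=57.0, tr_ms=8800.0, b0_T=3.0)


@pytest.fixture(scope="session")
def default_substrate():
    """One shared small synthetic brain (fraction map + tractogram)."""
    recipe = SubstrateRecipe.default(grid_shape=(40, 40, 40), rng_seed=0)
    vf, tractogram = generate_numerical_brain(recipe)
    return recipe, vf, tractogram


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
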