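import numpy as np
import pytest

from fragspec.chem import POSITIVE, parse_structure
from fragspec.fraggraph import build_graph
from fragspec.model import TransitionModel
from fragspec.simulate import FixtureConfig, generate_library, reference_models


@pytest.fixture(scope="session")
def water():
    return parse_structure("O")


@pytest.fixture(scope="session")
def ethanol():
    return parse_structure("CCO")


@pytest.fixture(scope="session")
def glycine():
    return parse_structure("NCC(=O)O")


@pytest.fixture(scope="session")
def ethanol_graph(ethanol):
    return build_graph(ethanol, POSITIVE, max_depth=2)


@pytest.fixture(scope="session")
def ref_models():
    return reference_models()


@pytest.fixture(scope="session")
def zero_model():
    return TransitionModel.zeros()


@pytest.fixture(scope="session")
def tiny_library():
    """Eight small molecules, fixed seed; cheap enough for per-test graphs."""
    cfg = FixtureConfig(n_molecules=8, heavy_atom_range=(3, 6), seed=7)
    return generate_library(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
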