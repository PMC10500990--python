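import numpy as np
import pytest

from lvcspec import (GeneratorConfig, make_displaced_monomer,
                     make_kasha_ct_dimer, make_random_lvc)


@pytest.fixture
def monomer():
    """One bright state, S = 0.5, w = 0.15 eV, E_v = 2.0 eV."""
    return make_displaced_monomer()


@pytest.fixture
def dimer():
    """4 LE + 4 CT stacked-dimer template with default couplings."""
    return make_kasha_ct_dimer()


@pytest.fixture
def random_model():
    def _make(seed, **kwargs):
        return make_random_lvc(GeneratorConfig(seed=seed, **kwargs))
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
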