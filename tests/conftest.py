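import numpy as np
import pytest

from residuehd import make_modulus_base, make_residue_base


@pytest.fixture(scope="session")
def base5():
    """Modulus-5 base at moderate dimension, full-range sampling."""
    return make_modulus_base(5, 1024, seed=11)


@pytest.fixture(scope="session")
def base5_nonzero():
    return make_modulus_base(5, 1024, nonzero_only=True, seed=12)


@pytest.fixture(scope="session")
def rb357():
    """Residue base {3,5,7} (M=105) with nonzero sampling for anti-bases."""
    return make_residue_base([3, 5, 7], 1024, nonzero_only=True, seed=13)


@pytest.fixture(scope="session")
def rb357_small():
    return make_residue_base([3, 5, 7], 256, nonzero_only=True, seed=14)


@pytest.fixture(scope="session")
def rb35():
    return make_residue_base([3, 5], 512, nonzero_only=True, seed=15)
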