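import numpy as np
import pytest

from piefm import fixtures as fx
from piefm import split_reversible
from piefm.oracle import enumerate_bruteforce


@pytest.fixture(scope="session")
def diamond():
    return fx.make_diamond()


@pytest.fixture(scope="session")
def lin():
    """One metabolite, one import, two exits: EFMs {r1,r2}, {r1,r3}."""
    return fx.toy_lin()


@pytest.fixture(scope="session")
def rev_split():
    """->A, A<->B, B-> after reversible splitting (4 columns)."""
    return split_reversible(fx.make_reversible_chain())


@pytest.fixture(scope="session")
def diamond_efms(diamond):
    """The diamond's two EFMs from the brute-force oracle, as supports."""
    return sorted(
        enumerate_bruteforce(diamond).supports(), key=lambda s: sorted(s)
    )


@pytest.fixture(scope="session")
def random_nets():
    """25 seeded random networks (<= 12 reactions after blocked removal)."""
    return [fx.make_random(4, 10, 0.35, seed) for seed in range(25)]
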