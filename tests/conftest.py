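import pytest

from phylocat.core import OrthogroupAlignment, OrthogroupSet, TaxonUniverse
from phylocat.simulate import SimParams, simulate_dataset


@pytest.fixture
def toy_universe():
    return TaxonUniverse(["A", "B", "C", "D"])


@pytest.fixture
def toy_set(toy_universe):
    """Two small hand-built loci over four taxa; D absent from og1."""
    og1 = OrthogroupAlignment("og1", {"A": "MKR-A", "B": "MKRTA", "C": "MQRTA"})
    og2 = OrthogroupAlignment(
        "og2", {"A": "WWCCHHH", "B": "WWCCHHH", "C": "WYCCHKH", "D": "WYCCHKR"}
    )
    return OrthogroupSet(toy_universe, [og1, og2])


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated dataset shared across tests."""
    return simulate_dataset(SimParams(seed=1))
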