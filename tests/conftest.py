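import numpy as np
import pytest

from heltrace.simulate import (
    HelitronSpec,
    ProviralLocusSpec,
    gen_helitron,
    gen_proviral_locus,
    random_dna,
)


@pytest.fixture(scope="session")
def default_helitron():
    """Default synthetic Helitron (record, truth), generated once."""
    return gen_helitron(HelitronSpec(), seed=1)


@pytest.fixture(scope="session")
def default_locus():
    """Default proviral-locus fixture (record, truth), generated once."""
    return gen_proviral_locus(ProviralLocusSpec(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_dna(seed: int, n: int, gc: float = 0.4) -> str:
    return random_dna(np.random.default_rng(seed), n, gc)
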