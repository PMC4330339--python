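import random

import pytest

from grasp.alphabet import ReducedAlphabet
from grasp.scoring import ScoringScheme
from grasp.seqio import AMINO_ACIDS, ReadSet


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def narrow_scheme():
    """Small band for exercising band-edge behaviour cheaply."""
    return ScoringScheme(d=8)


@pytest.fixture(scope="session")
def murphy10():
    return ReducedAlphabet.preset("murphy10")


@pytest.fixture
def rng():
    return random.Random(20240901)


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def random_readset(rng: random.Random, n_reads: int, max_len: int) -> ReadSet:
    return ReadSet(
        (f"r{i}", random_protein(rng, rng.randint(1, max_len)))
        for i in range(n_reads)
    )
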