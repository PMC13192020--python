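import numpy as np
import pytest
from hypothesis import settings

from satkit.records import SatFamily

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def consensus_142() -> str:
    return random_dna(142, 7)


@pytest.fixture
def family(consensus_142) -> SatFamily:
    return SatFamily("TmSat01", consensus_142)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
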