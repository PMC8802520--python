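import numpy as np
import pytest

from dnactx import Genome
from dnactx.synthetic_data import make_toy_fixture

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    seq = _BASES[rng.integers(0, 4, length)].copy()
    if n_prob > 0:
        seq[rng.random(length) < n_prob] = "N"
    return "".join(seq)


def random_genome(rng: np.random.Generator, length: int, n_records: int = 1,
                  n_prob: float = 0.0) -> Genome:
    per = length // n_records
    return Genome((f"c{i + 1}", random_seq(rng, per, n_prob))
                  for i in range(n_records))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy():
    return make_toy_fixture()
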