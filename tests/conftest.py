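import numpy as np
import pytest

from mitocompare.genome import CircularSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(seed: int, length: int, gc: float = 0.45, ident: str = "g") -> CircularSequence:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    return CircularSequence(id=ident, residues="".join(bases[rng.choice(4, size=length, p=p)]))
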