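import numpy as np
import pytest

from evorescue.diversity import GeneAlignment

BASES = "ACGT"


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     gene_id: str = "g", missing_rate: float = 0.0) -> GeneAlignment:
    """Random alignment mixing invariant and mutated columns, optional missing data."""
    seqs = []
    ref = rng.integers(0, 4, size=length)
    for i in range(n):
        row = ref.copy()
        flip = rng.random(length) < 0.3
        row[flip] = rng.integers(0, 4, size=int(flip.sum()))
        chars = [BASES[b] for b in row]
        if missing_rate > 0:
            miss = rng.random(length) < missing_rate
            chars = ["N" if m else c for c, m in zip(chars, miss)]
        seqs.append("".join(chars))
    return GeneAlignment.from_sequences(gene_id, [f"s{i}" for i in range(n)], seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20151003)
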