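import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from operscan import GenomeSequence, random_energy_matrix


@pytest.fixture
def consensus_operator_genome():
    """A 16-bp genome that is exactly one consensus operator."""
    return GenomeSequence("mini", "TTAAGACGATCTTAAG")


@pytest.fixture
def truth_matrix():
    """A fixed random ground-truth energy matrix."""
    return random_energy_matrix(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genome(rng, length, gc=0.66, contig_id="chr", circular=False):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return GenomeSequence(contig_id, seq, circular=circular)
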