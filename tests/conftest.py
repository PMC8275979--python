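import itertools

import numpy as np
import pytest

from backgen.composition import kmer_profile
from backgen.seqio import SequenceRecord

IUPAC = "ACGTRYSWKMBDHVN"


def random_iupac_sequence(rng: np.random.Generator, length: int, alphabet_size: int = 4) -> str:
    """Random sequence over a random subset of the IUPAC alphabet."""
    size = min(alphabet_size, len(IUPAC))
    letters = rng.choice(list(IUPAC), size=size, replace=False)
    return "".join(rng.choice(letters, size=length))


def brute_force_rearrangements(s: str, k: int) -> set[str]:
    """All distinct permutations of s with the same k-mer counts (oracle)."""
    target = kmer_profile(s, k)
    return {
        "".join(p)
        for p in set(itertools.permutations(s))
        if kmer_profile("".join(p), k) == target
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def make_record():
    def _make(residues: str, identifier: str = "seq", description: str = "") -> SequenceRecord:
        return SequenceRecord(identifier, description, residues)

    return _make
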