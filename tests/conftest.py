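from pathlib import Path

import numpy as np
import pytest

from aavec import AlphabetConfig, ProteinSequence
from aavec.fixtures import random_sequence

#: Optional user-supplied FASTA of the nine ND5 benchmark proteins
#: (NCBI accessions in the README).  Tests depending on it skip cleanly
#: when it is absent.
ND5_FASTA = Path(__file__).resolve().parent.parent / "data" / "nd5.fasta"


@pytest.fixture
def alphabet() -> AlphabetConfig:
    return AlphabetConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260906)


@pytest.fixture
def random_seqs(rng, alphabet) -> list[ProteinSequence]:
    lengths = [2, 3, 21, 57, 300, 605]
    return [
        random_sequence(rng, n, alphabet, label=f"rand{i}_{n}")
        for i, n in enumerate(lengths)
    ]


@pytest.fixture
def nd5_fasta_path() -> Path:
    if not ND5_FASTA.exists():
        pytest.skip(
            "ND5 benchmark sequences not present (place the nine NCBI "
            f"protein sequences at {ND5_FASTA} to enable)"
        )
    return ND5_FASTA
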