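import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from triplexhub.io import NucleicSequence


def rna(residues: str, id: str = "rna") -> NucleicSequence:
    return NucleicSequence(id=id, residues=residues, kind="RNA")


def dna(residues: str, id: str = "dna") -> NucleicSequence:
    return NucleicSequence(id=id, residues=residues, kind="DNA")


def random_rna(rng: np.random.Generator, length: int, alphabet: str = "ACGU") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
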