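import numpy as np
import pytest

from lectnet.dca import ALPHABET, Alignment
from lectnet.structure import Atom, Structure


@pytest.fixture
def two_atom_pdb() -> str:
    return (
        "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C\n"
        "ATOM      2  CB  ALA A   1      12.560   6.351  -6.104  1.00  0.00           C\n"
        "END\n"
    )


@pytest.fixture
def water_only_pdb() -> str:
    return (
        "HETATM    1  O   HOH A 101      11.104   6.134  -6.504  1.00  0.00           O\n"
        "HETATM    2  O   HOH A 102      14.104   6.134  -6.504  1.00  0.00           O\n"
        "END\n"
    )


def make_alignment(seqs: list[str], ids: list[str] | None = None) -> Alignment:
    code = {c: i for i, c in enumerate(ALPHABET)}
    mat = np.array([[code.get(ch, 0) for ch in s.upper()] for s in seqs], dtype=np.int8)
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    return Alignment(ids, mat)


def single_atom_structure(element: str = "C") -> Structure:
    return Structure([Atom("A", 1, "ALA", "CA", element)], np.zeros((1, 1, 3)))


@pytest.fixture
def aln_factory():
    return make_alignment
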