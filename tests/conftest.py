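import numpy as np
import pytest

from barcodekit.records import SequenceRecord


def rec(id, species, seq, individual="V01", locus="LOC", accession=""):
    return SequenceRecord(id=id, species=species, individual=individual,
                          locus=locus, seq=seq, accession=accession)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_species_alignment():
    """2 species x 2 identical-within-species rows, distinct between."""
    return [
        rec("a1", "Alpha one", "ACGTACGTACGT"),
        rec("a2", "Alpha one", "ACGTACGTACGT", individual="V02"),
        rec("b1", "Beta two", "ACGTACGTAAAA"),
        rec("b2", "Beta two", "ACGTACGTAAAA", individual="V02"),
    ]


def random_sequences(rng, n, length, alphabet="ACGT"):
    letters = np.array(list(alphabet))
    return ["".join(letters[rng.integers(0, len(letters), length)]) for _ in range(n)]
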