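import numpy as np
import pytest

from tapirgeo.seq_io import HaplotypeTable, SequenceAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20100914)


@pytest.fixture
def toy_alignment():
    return SequenceAlignment(
        [
            ("s1", "ACGTACGTAC"),
            ("s2", "ACGTACGTAC"),
            ("s3", "ACGAACGTAC"),
            ("s4", "ACGAACGTAT"),
        ]
    )


@pytest.fixture
def triplet_haplotypes():
    """The worked median-joining triplet: pairwise distance 2, median AAG."""
    return HaplotypeTable(
        [("H1", "AAA"), ("H2", "AGG"), ("H3", "GAG")],
        ["all"],
        np.array([[1], [1], [1]]),
    )


def random_alignment(rng, n, L, alphabet="ACGT"):
    mat = rng.choice(list(alphabet), size=(n, L))
    return SequenceAlignment([(f"s{i}", "".join(row)) for i, row in enumerate(mat)])
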