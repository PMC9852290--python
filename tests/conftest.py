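import numpy as np
import pytest

from rablchrom.michrom import GenomeSpec, MiChroMParameters


@pytest.fixture
def small_spec():
    """Single 12-bead chromosome, alternating AB blocks of 3."""
    return GenomeSpec(
        n_beads=12,
        bin_size=100_000,
        chrom_of=np.zeros(12, dtype=int),
        type_of=np.array(list("AAABBBAAABBB")),
        telomere_beads=np.array([0, 11]),
        centromere_beads=np.array([5, 6]),
    )


@pytest.fixture
def two_chrom_spec():
    """Two 10-bead chromosomes."""
    return GenomeSpec(
        n_beads=20,
        bin_size=100_000,
        chrom_of=np.repeat([0, 1], 10),
        type_of=np.array(list("AAAAABBBBB" * 2)),
        telomere_beads=np.array([0, 9, 10, 19]),
        centromere_beads=np.array([4, 5, 14, 15]),
    )


@pytest.fixture
def default_params():
    return MiChroMParameters(d_cutoff=10)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
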