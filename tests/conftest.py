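import numpy as np
import pytest

from vellum.sequence_io import Contig, GenomeDB, Read


@pytest.fixture
def toy_genome_db():
    """Two small diverged genomes plus an identical pair for symmetry checks."""
    db = GenomeDB()
    db.add_genome("alpha", [Contig("chr1", "ACGTACGTTACGGATTACAGGCATGCA" * 40)])
    db.add_genome("beta", [Contig("chr1", "ACGAACGTTACGGATTTCAGGCATGAA" * 40)])
    return db


@pytest.fixture
def q35():
    def make(seq, read_id="r1"):
        return Read(read_id, seq, (35,) * len(seq))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
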