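import numpy as np
import pytest

from suvrkit import synthetic


@pytest.fixture(scope="session")
def toy_genome():
    return synthetic.make_genome(seed=1)


@pytest.fixture(scope="session")
def planted_genome():
    genome = synthetic.make_genome(seed=1)
    genome, truth = synthetic.plant_motif_sites(genome, gene_fraction=0.4,
                                                upstream_window=1000, seed=2)
    return genome, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_reads(rng, n, length, planted=None, fraction=0.0):
    """Uniform random reads with an optional planted word in a fraction of them."""
    bases = np.array(list("ACGT"))
    reads = []
    n_planted = int(round(fraction * n))
    for i in range(n):
        read = "".join(bases[rng.integers(0, 4, length)])
        if planted and i < n_planted:
            j = int(rng.integers(0, length - len(planted) + 1))
            read = read[:j] + planted + read[j + len(planted):]
        reads.append(read)
    return reads
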