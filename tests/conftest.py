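import numpy as np
import pytest

from sctad.hic_io import ContactMatrix, DomainSet


def block_matrix(n, block_size, enrichment=5.0, decay=1.0, background=1.0):
    """Noiseless expected Hi-C of equal blocks: power-law distance decay
    times a within-block enrichment factor."""
    labels = np.arange(n) // block_size
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    base = (1.0 + dist) ** -decay if decay > 0 else np.ones((n, n))
    return base * np.where(labels[:, None] == labels[None, :],
                           enrichment, background)


@pytest.fixture
def ten_block_matrix():
    """200-bin noiseless matrix with 10 equal 20-bin blocks."""
    return block_matrix(200, 20)


@pytest.fixture
def two_block_consensus():
    """Perfect 40-bin consensus map of two 20-bin clusters."""
    from sctad.detector import ConsensusMap
    lab = np.repeat([0, 1], 20)
    return ConsensusMap(C=(lab[:, None] == lab[None, :]).astype(float), k=10)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 20, (20, 20)).astype(float)
    m = np.triu(a) + np.triu(a, 1).T
    return ContactMatrix("chr1", 40_000, m)


def make_domains(domains, n_bins, binsize=40_000, chrom="chr1"):
    return DomainSet(chrom, binsize, n_bins, domains)
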