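import numpy as np
import pytest

from promloop.core import GenomicInterval
from promloop.simulate import make_toy_gene_model


@pytest.fixture(scope="session")
def toy_model():
    """Small deterministic gene model shared by read-level tests."""
    model, seq = make_toy_gene_model(genome_length=200_000, n_start_exons=7, seed=7)
    return model, seq


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def iv(start, end, chrom="chrS", strand="."):
    return GenomicInterval(chrom, start, end, strand)
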