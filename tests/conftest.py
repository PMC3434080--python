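import numpy as np
import pytest

from asbcall.core import Read
from asbcall.sim_data import SimConfig, simulate


def make_read(name, start, seq, mapq=37, strand="+", bq=30, chrom="chr1",
              cigar=None):
    quals = np.full(len(seq), bq, dtype=np.uint8)
    return Read(name=name, chrom=chrom, start=start, mapq=mapq,
                strand=strand, seq=seq, quals=quals,
                cigar=cigar or (("M", len(seq)),))


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated experiment shared across tests."""
    cfg = SimConfig(genome_length=40_000, n_snps=160, n_peaks=6,
                    peak_width=1000, min_spacing=60, seed=11)
    truth, reads = simulate(cfg)
    return cfg, truth, reads


@pytest.fixture()
def tiny_reference():
    return {"chr1": "ACGTACGTACGTACGTACGT"}
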