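import numpy as np
import pytest

from adpgen import (
    DloopSimConfig,
    GenotypeMatrix,
    SeqAlignment,
    simulate_dloop,
    synthetic_reference_cds,
)


@pytest.fixture(scope="session")
def dloop_sim():
    """Default two-clade control-region simulation plus its truth tables."""
    return simulate_dloop(DloopSimConfig(seed=7))


@pytest.fixture(scope="session")
def clade_panel(dloop_sim):
    """The two clade root sequences as a labelled reference panel."""
    _, truth = dloop_sim
    panel = SeqAlignment(list(truth.clade_roots), list(truth.clade_roots.values()))
    return panel, dict(zip(truth.clade_roots, truth.clade_roots))


@pytest.fixture(scope="session")
def mc1r_reference():
    return synthetic_reference_cds()


def make_gm(calls, chrom=None, pos=None, sample_ids=None, snp_ids=None):
    """GenotypeMatrix from a raw dosage array with sensible defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    snp_ids = snp_ids or [f"m{j + 1}" for j in range(m)]
    chrom = np.asarray(chrom if chrom is not None else ["1"] * m, dtype=object)
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1) * 100_000)
    return GenotypeMatrix(sample_ids, snp_ids, chrom, pos, [("A", "B")] * m, calls)


@pytest.fixture()
def qc_toy_matrix():
    """Hand-constructed 20-sample x 10-SNP matrix with known QC outcome.

    Removal counts under the default 10%/5%/10% thresholds, by hand:
    m1, m2 are missing in 3/20 samples (15% > 10%)     -> 2 SNPs at stage 1
    m3-m5 carry one het in 20 samples (MAF 1/40 = 0.025) -> 3 SNPs at stage 2
    s20 is missing at m6, m7 (each 1/20 = 5%, SNPs kept) and so misses
    2 of the 5 surviving SNPs (40% > 10%)               -> 1 sample at stage 3
    Result: 5 SNPs x 19 samples.
    """
    n, m = 20, 10
    calls = np.zeros((n, m), dtype=np.int8)
    for i in range(n):            # balanced genotypes, MAF ~ 0.5
        calls[i, :] = (i % 3)
    calls[0, 2:5] = 1             # m3..m5: single het -> MAF 0.025
    calls[1:, 2:5] = 0
    calls[1:4, 0:2] = -1          # m1, m2: 15% missing
    calls[19, 5:7] = -1           # s20: misses 2 of the surviving 5 SNPs
    return make_gm(calls)
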