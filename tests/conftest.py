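import numpy as np
import pandas as pd
import pytest

from popkit.genotype_io import (
    GenotypeTable,
    IndividualRecord,
    SnpPanel,
    assign_blocks,
    build_group_counts,
)


def make_panel_df(n, chrom="1", spacing=100_000, genetic=None):
    pos = np.arange(1, n + 1) * spacing
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chromosome": chrom,
            "physical_pos": pos,
            "genetic_pos": pos * 1e-8 if genetic is None else genetic,
            "ref_allele": "A",
            "alt_allele": "C",
        }
    )


def random_table(rng, n_snps=20, n_ind=6, missing_rate=0.15, diploid=False):
    """Small random GenotypeTable for oracle comparisons."""
    df = make_panel_df(n_snps)
    mode = "diploid" if diploid else "pseudo-haploid"
    inds = [
        IndividualRecord(individual_id=f"i{j}", group_label=f"g{j % 3}", ploidy_mode=mode)
        for j in range(n_ind)
    ]
    top = 3 if diploid else 2
    calls = rng.integers(0, top, size=(n_snps, n_ind)).astype(np.int8)
    calls[rng.random((n_snps, n_ind)) < missing_rate] = 9
    return GenotypeTable(SnpPanel(df), inds, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return random_table(rng, n_snps=40, n_ind=8)


@pytest.fixture
def small_setup(small_table):
    grouping = {
        "A": ["i0", "i1", "i2"],
        "B": ["i3", "i4", "i5"],
        "C": ["i6", "i7"],
    }
    counts = build_group_counts(small_table, grouping)
    blocks = assign_blocks(small_table.panel, block_span_bp=1_000_000)
    return small_table, counts, blocks
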