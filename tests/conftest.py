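import numpy as np
import pandas as pd
import pytest

import riboprof as rp


@pytest.fixture(scope="session")
def small_config():
    return rp.SimConfig(
        seed=11, n_genes=20, library_size={a: 5_000 for a in rp.ASSAYS}
    )


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return rp.generate_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_transcriptome):
    return rp.annotation_frame(small_transcriptome)


def make_fragments(rows):
    """Fragment frame from (transcript_id, start, end, assay, replicate) tuples."""
    return pd.DataFrame(
        [(*r, "wt") for r in rows],
        columns=["transcript_id", "start", "end", "assay", "replicate", "genotype"],
    )


@pytest.fixture
def toy_annotation():
    return pd.DataFrame(
        {"utr5_len": [100, 50], "cds_len": [300, 150], "utr3_len": [100, 50]},
        index=pd.Index(["geneA", "geneB"], name="gene_id"),
    )


def brute_force_counts(fragments: pd.DataFrame) -> dict:
    """Independent per-record tally: (gene, assay, replicate) -> count."""
    tally: dict = {}
    for row in fragments.itertuples(index=False):
        key = (row.transcript_id, row.assay, row.replicate)
        tally[key] = tally.get(key, 0) + 1
    return tally


def brute_force_coverage(fragments: pd.DataFrame, length: int) -> np.ndarray:
    """Per-base coverage array built fragment by fragment."""
    cov = np.zeros(length)
    for row in fragments.itertuples(index=False):
        cov[row.start : row.end] += 1
    return cov
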