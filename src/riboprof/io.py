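"""File dialects: FASTA sequences, TSV annotation/fragment/count tables, SAM.

Everything tabular is tab-separated with a header row and documented column
order; intervals are 0-based half-open in transcript coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quantify import FRAGMENT_COLUMNS, CountTable, ExpressionTable
from .simulate import TranscriptModel

FLOAT_FORMAT = "%.10g"  # stable text round-trips: identical runs, identical bytes


def write_fasta(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    required = {"utr5_len", "cds_len", "utr3_len"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation lacks columns {sorted(missing)}")
    return frame


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments.to_csv(path, sep="\t", index=False, columns=FRAGMENT_COLUMNS)


def read_fragments(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"transcript_id": str, "start": np.int64, "end": np.int64,
               "assay": str, "replicate": np.int64, "genotype": str},
    )
    missing = set(FRAGMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"fragment table lacks columns {sorted(missing)}")
    return frame[FRAGMENT_COLUMNS]


def fragments_from_sam(
    path: str | Path, assay: str, replicate: int, genotype: str = "wt"
) -> pd.DataFrame:
    """Adapter: mapped SAM/BAM records (transcript references) -> fragments."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for read in handle.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            rows.append(
                (read.reference_name, read.reference_start, read.reference_end,
                 assay, replicate, genotype)
            )
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def _long_counts(table: CountTable) -> pd.DataFrame:
    long = (
        table.counts.stack(["assay", "replicate"], future_stack=True)
        .rename("count")
        .reset_index()
    )
    return long.sort_values(["gene_id", "assay", "replicate"], ignore_index=True)


def write_count_table(table: CountTable, counts_path, totals_path) -> None:
    _long_counts(table).to_csv(counts_path, sep="\t", index=False)
    table.total_mapped.rename("total_mapped").reset_index().to_csv(
        totals_path, sep="\t", index=False
    )


def read_count_table(counts_path, totals_path) -> CountTable:
    long = pd.read_csv(counts_path, sep="\t")
    counts = long.pivot_table(
        index="gene_id", columns=["assay", "replicate"], values="count",
        fill_value=0, aggfunc="sum",
    ).astype(np.int64)
    totals_frame = pd.read_csv(totals_path, sep="\t")
    totals = totals_frame.set_index(["assay", "replicate"])["total_mapped"]
    return CountTable(counts=counts, total_mapped=totals)


def write_expression_table(expr: ExpressionTable, path) -> None:
    long = (
        expr.rpkm.stack(["assay", "replicate"], future_stack=True)
        .rename("rpkm")
        .reset_index()
        .sort_values(["gene_id", "assay", "replicate"], ignore_index=True)
    )
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_table(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
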