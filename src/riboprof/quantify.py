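"""Fragment tables -> counts, RPKM, region coverage and replicate agreement.

Counts are unique-exon read tallies per gene x assay x replicate; RPKM is
reads per kilobase of exon per million mapped reads, normalized per replicate
library.  Genes are considered reliably detected only when every replicate of
an assay reaches ``min_reads`` (default 10), the threshold below which
measurement variability rises sharply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ASSAYS, TranscriptModel, UnknownGeneError

FRAGMENT_COLUMNS = ["transcript_id", "start", "end", "assay", "replicate", "genotype"]


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned read fragment in 0-based half-open transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    assay: str
    replicate: int
    genotype: str = "wt"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")


def fragments_to_frame(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=FRAGMENT_COLUMNS)


def frame_to_fragments(frame: pd.DataFrame) -> list[FragmentRecord]:
    return [
        FragmentRecord(
            str(r.transcript_id), int(r.start), int(r.end), str(r.assay),
            int(r.replicate), str(r.genotype),
        )
        for r in frame.itertuples(index=False)
    ]


def annotation_frame(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Segment-length annotation table (index gene_id) from transcript models.

    Entries mapped onto a parent transcript (residual fragments) do not get
    their own row: their reads are reported under the parent's id.
    """
    rows = {}
    for t in transcripts:
        if t.parent_id is not None:
            continue
        rows[t.gene_id] = (t.utr5_len, t.cds_len, t.utr3_len)
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["utr5_len", "cds_len", "utr3_len"]
    )
    frame.index.name = "gene_id"
    return frame


def exon_lengths(annotation: pd.DataFrame) -> pd.Series:
    """Total exon (transcript) length per gene."""
    return annotation[["utr5_len", "cds_len", "utr3_len"]].sum(axis=1)


def validate_fragments(fragments: pd.DataFrame, annotation: pd.DataFrame) -> None:
    missing = [c for c in FRAGMENT_COLUMNS[:5] if c not in fragments.columns]
    if missing:
        raise ValueError(f"fragment table lacks columns {missing}")
    ids = pd.Index(fragments["transcript_id"].unique())
    unknown = sorted(ids.difference(annotation.index))
    if unknown:
        raise UnknownGeneError(
            f"fragments reference unannotated transcripts: {unknown[:10]}"
            + ("..." if len(unknown) > 10 else "")
        )
    if len(fragments):
        lengths = exon_lengths(annotation)
        tlen = fragments["transcript_id"].map(lengths).to_numpy()
        start = fragments["start"].to_numpy()
        end = fragments["end"].to_numpy()
        bad = (start < 0) | (start >= end) | (end > tlen)
        if bad.any():
            rows = fragments.loc[bad, ["transcript_id", "start", "end"]].head(5)
            raise ValueError(f"fragments out of transcript bounds:\n{rows}")


@dataclass
class CountTable:
    """Per gene x (assay, replicate) unique-exon counts with library totals."""

    counts: pd.DataFrame  # index gene_id, columns MultiIndex (assay, replicate)
    total_mapped: pd.Series  # index MultiIndex (assay, replicate)

    def replicates(self, assay: str) -> list[int]:
        if assay not in self.counts.columns.get_level_values(0):
            return []
        return sorted(self.counts[assay].columns)


@dataclass
class ExpressionTable:
    """RPKM per gene x (assay, replicate), plus exon lengths and totals."""

    rpkm: pd.DataFrame
    exon_len: pd.Series
    total_mapped: pd.Series

    def mean(self, assay: str) -> pd.Series:
        """Replicate-mean RPKM for one assay."""
        return self.rpkm[assay].mean(axis=1)


def count_reads(
    fragments: pd.DataFrame,
    annotation: pd.DataFrame,
    genotype: str | None = None,
) -> CountTable:
    """Tally fragments into a gene x assay x replicate count table.

    Each fragment increments exactly one gene (assignment by transcript id);
    ``total_mapped`` per assay/replicate is the number of fragments processed.
    All annotated genes appear as rows (zero-filled).
    """
    if genotype is not None and "genotype" in fragments.columns:
        fragments = fragments[fragments["genotype"] == genotype]
    elif "genotype" in fragments.columns and len(fragments):
        present = fragments["genotype"].unique()
        if len(present) > 1:
            raise ValueError(
                f"fragment table mixes genotypes {sorted(present)}; pass genotype="
            )
    validate_fragments(fragments, annotation)
    if not len(fragments):
        counts = pd.DataFrame(
            index=annotation.index,
            columns=pd.MultiIndex.from_tuples([], names=["assay", "replicate"]),
            dtype=np.int64,
        )
        totals = pd.Series(
            [], index=pd.MultiIndex.from_tuples([], names=["assay", "replicate"]),
            dtype=np.int64,
        )
        return CountTable(counts, totals)

    grouped = fragments.groupby(["transcript_id", "assay", "replicate"]).size()
    counts = (
        grouped.unstack(["assay", "replicate"], fill_value=0)
        .reindex(annotation.index, fill_value=0)
        .astype(np.int64)
        .sort_index(axis=1)
    )
    counts.columns.names = ["assay", "replicate"]
    counts.index.name = "gene_id"
    totals = fragments.groupby(["assay", "replicate"]).size().sort_index()
    totals.index.names = ["assay", "replicate"]
    return CountTable(counts, totals)


def filter_expressed(
    table: CountTable, assay: str, min_reads: int = 10
) -> set[str]:
    """Genes with >= ``min_reads`` in every replicate of ``assay``."""
    if assay not in table.counts.columns.get_level_values(0):
        raise ValueError(f"count table has no replicates for assay {assay!r}")
    sub = table.counts[assay]
    passing = sub.index[(sub >= min_reads).all(axis=1)]
    return set(passing)


def expressed_gene_sets(
    table: CountTable, min_reads: int = 10
) -> dict[str, set[str]]:
    """Reliably detected gene set per assay present in the table."""
    return {
        assay: filter_expressed(table, assay, min_reads)
        for assay in sorted(set(table.counts.columns.get_level_values(0)))
    }


def compute_rpkm(
    table: CountTable,
    exon_len: pd.Series,
    total_mapped: pd.Series | Mapping | None = None,
) -> ExpressionTable:
    """RPKM = count / ((exon_len/1e3) * (total_mapped/1e6)) per cell.

    ``total_mapped`` defaults to the per-replicate totals observed in the
    table; pass nominal (depth-calibrated) totals instead when absolute
    between-library comparisons are intended.
    """
    exon_len = exon_len.reindex(table.counts.index)
    if exon_len.isna().any() or (exon_len <= 0).any():
        raise ValueError("exon_len must be > 0 for every gene in the table")
    totals = table.total_mapped if total_mapped is None else pd.Series(total_mapped)
    if len(table.counts.columns):
        totals = totals.reindex(table.counts.columns)
        if totals.isna().any() or (totals <= 0).any():
            raise ValueError("total_mapped must be > 0 for every assay/replicate")
    denom = np.outer(exon_len.to_numpy() / 1e3, totals.to_numpy() / 1e6)
    rpkm = pd.DataFrame(
        table.counts.to_numpy() / denom if len(table.counts.columns) else table.counts,
        index=table.counts.index,
        columns=table.counts.columns,
        dtype=float,
    )
    return ExpressionTable(rpkm=rpkm, exon_len=exon_len, total_mapped=totals)


def gene_regions(annotation: pd.DataFrame, gene_id: str) -> list[tuple[str, tuple[int, int]]]:
    """The (utr5, cds, utr3) intervals of a gene, 0-based half-open."""
    row = annotation.loc[gene_id]
    u5, cds, u3 = int(row["utr5_len"]), int(row["cds_len"]), int(row["utr3_len"])
    return [
        ("utr5", (0, u5)),
        ("cds", (u5, u5 + cds)),
        ("utr3", (u5 + cds, u5 + cds + u3)),
    ]


def _region_mass(fragments: pd.DataFrame, interval: tuple[int, int]) -> float:
    """Total per-base coverage mass of fragments falling inside an interval."""
    a, b = interval
    if not len(fragments) or b <= a:
        return 0.0
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    overlap = np.minimum(end, b) - np.maximum(start, a)
    return float(np.clip(overlap, 0, None).sum())


def region_coverage_fractions(
    fragments: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_id: str,
) -> tuple[float, float, float]:
    """Fraction of a gene's per-base coverage mass in (5'UTR, CDS, 3'UTR).

    Fractions sum to 1 when the gene has any coverage; with zero coverage the
    result is (nan, nan, nan) and a warning is issued.
    """
    if gene_id not in annotation.index:
        raise UnknownGeneError(gene_id)
    sub = fragments[fragments["transcript_id"] == gene_id]
    masses = [
        _region_mass(sub, iv) for _, iv in gene_regions(annotation, gene_id)
    ]
    total = sum(masses)
    if total == 0:
        warnings.warn(f"{gene_id}: zero coverage, region fractions undefined")
        return (float("nan"),) * 3
    return tuple(m / total for m in masses)  # type: ignore[return-value]


@dataclass
class RegionExpression:
    """Per-region expression of a case library normalized to a reference."""

    regions: list[tuple[str, tuple[int, int]]]
    values: dict[str, float]  # nan where the reference region has no mass


def region_partition_expression(
    case_fragments: pd.DataFrame,
    reference_fragments: pd.DataFrame,
    regions: Sequence[tuple[str, tuple[int, int]]],
    case_library_size: float,
    reference_library_size: float,
) -> RegionExpression:
    """Library-size-normalized per-region expression relative to a reference.

    value(region) = (case region density / case library size)
                  / (reference region density / reference library size).
    A reference region with zero mass yields nan (undefined).
    """
    regions = list(regions)
    for _, (a, b) in regions:
        if a >= b:
            raise ValueError("regions must be non-empty intervals")
    for (_, (_, b1)), (_, (a2, _)) in zip(regions, regions[1:]):
        if b1 > a2:
            raise ValueError("regions must be disjoint, ordered intervals")
    if case_library_size <= 0 or reference_library_size <= 0:
        raise ValueError("library sizes must be > 0")
    values = {}
    for label, interval in regions:
        case = _region_mass(case_fragments, interval) / case_library_size
        ref = _region_mass(reference_fragments, interval) / reference_library_size
        values[label] = case / ref if ref > 0 else float("nan")
    return RegionExpression(regions=regions, values=values)


def replicate_correlation(
    expr: ExpressionTable,
    assay: str,
    rep_a: int,
    rep_b: int,
    log_transform: bool = True,
    genes: Iterable[str] | None = None,
) -> float:
    """Coefficient of determination (r^2) between two replicate libraries.

    Computed on log10 RPKM by default, matching how replicate scatter is
    usually assessed; genes without finite (positive, for log) values in both
    replicates are dropped.  Requires >= 3 usable genes.
    """
    sub = expr.rpkm[assay]
    x = sub[rep_a].astype(float)
    y = sub[rep_b].astype(float)
    if genes is not None:
        keep = sub.index.intersection(pd.Index(genes))
        x, y = x.loc[keep], y.loc[keep]
    mask = np.isfinite(x) & np.isfinite(y)
    if log_transform:
        mask &= (x > 0) & (y > 0)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need >= 3 genes with finite values in both replicates")
    if log_transform:
        x, y = np.log10(x), np.log10(y)
    r, _ = stats.pearsonr(x, y)
    return float(r**2)
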