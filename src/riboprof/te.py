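"""Translation efficiency: computation, categories, sensitivity, metagene.

TE is the ratio of translational to transcriptional expression: ribosome
profiling (or TRAP) RPKM divided by total-RNA RPKM for the same gene.  Genes
are classified as high (TE > 2), low (TE < 0.5) or medium (in between,
boundaries inclusive).  Per-gene TE uses replicate-mean RPKM in numerator and
denominator; per-replicate TEs are also provided for replicate-level tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ExpressionTable
from .simulate import UnknownGeneError

logger = logging.getLogger(__name__)

TE_HIGH = 2.0
TE_LOW = 0.5

CATEGORIES = ("high", "medium", "low")


@dataclass
class TERecord:
    """Per-gene translation efficiency values and category label."""

    gene_id: str
    te_ribo: float
    te_trap: float | None
    te_mean: float
    category: str


@dataclass
class MetageneProfile:
    """Averaged normalized per-base coverage around a common anchor."""

    anchor: str  # "start_codon" | "stop_codon"
    offsets: np.ndarray  # positions relative to the anchor, contiguous
    density: np.ndarray  # mean normalized coverage at each offset
    n_genes: int


def compute_te(ribo_rpkm, transcr_rpkm):
    """TE = translational RPKM / transcriptional RPKM (element-wise).

    Transcriptional RPKM must be > 0: genes failing the expression filter
    should never reach this computation.
    """
    ribo = np.asarray(ribo_rpkm, dtype=float)
    transcr = np.asarray(transcr_rpkm, dtype=float)
    if np.any(transcr <= 0):
        raise ValueError("TE undefined: transcriptional RPKM must be > 0")
    out = ribo / transcr
    if isinstance(ribo_rpkm, pd.Series):
        return pd.Series(out, index=ribo_rpkm.index)
    return out if out.ndim else float(out)


def classify_te(te, high: float = TE_HIGH, low: float = TE_LOW):
    """Map TE to {high, medium, low}; the boundaries belong to medium."""
    arr = np.asarray(te, dtype=float)
    if np.any(arr < 0):
        raise ValueError("TE must be >= 0")
    out = np.select([arr > high, arr < low], ["high", "low"], default="medium")
    if arr.ndim == 0:
        return str(out)
    if isinstance(te, pd.Series):
        return pd.Series(out, index=te.index)
    return out


def te_table(
    expr: ExpressionTable,
    genes=None,
    ribo_assay: str = "footprint",
    rna_assay: str = "total_rna",
    trap_assay: str | None = "trap",
    high: float = TE_HIGH,
    low: float = TE_LOW,
) -> pd.DataFrame:
    """Per-gene TE table (te_ribo, te_trap, te_mean, category).

    ``te_mean`` is the TE computed from replicate-mean RPKMs of the ribosome
    profiling assay; the category is assigned from it.
    """
    assays = set(expr.rpkm.columns.get_level_values(0))
    if ribo_assay not in assays or rna_assay not in assays:
        raise ValueError(f"expression table lacks {ribo_assay!r} or {rna_assay!r}")
    index = expr.rpkm.index if genes is None else pd.Index(sorted(genes))
    rna = expr.mean(rna_assay).reindex(index)
    ribo = expr.mean(ribo_assay).reindex(index)
    te_ribo = compute_te(ribo, rna)
    frame = pd.DataFrame({"te_ribo": te_ribo}, index=index)
    if trap_assay is not None and trap_assay in assays:
        frame["te_trap"] = compute_te(expr.mean(trap_assay).reindex(index), rna)
    else:
        frame["te_trap"] = np.nan
    frame["te_mean"] = frame["te_ribo"]
    frame["category"] = classify_te(frame["te_mean"], high=high, low=low)
    frame.index.name = "gene_id"
    return frame


def per_replicate_te(
    expr: ExpressionTable,
    genes=None,
    ribo_assay: str = "footprint",
    rna_assay: str = "total_rna",
) -> pd.DataFrame:
    """Per-gene, per-replicate TE (replicates paired by index)."""
    ribo = expr.rpkm[ribo_assay]
    rna = expr.rpkm[rna_assay]
    reps = sorted(set(ribo.columns) & set(rna.columns))
    if not reps:
        raise ValueError("no shared replicate indices between assays")
    index = ribo.index if genes is None else pd.Index(sorted(genes))
    out = {}
    for rep in reps:
        out[rep] = compute_te(ribo[rep].reindex(index), rna[rep].reindex(index))
    frame = pd.DataFrame(out, index=index)
    frame.index.name = "gene_id"
    frame.columns.name = "replicate"
    return frame


def percent_sensitivity(mean_log2_ratio: float) -> float:
    """Convert a mean log2 TE ratio to a percent sensitivity difference.

    A mean log2(ribo/TRAP) ratio of magnitude m corresponds to one method
    reporting (2^m - 1) x 100 percent larger efficiency changes; the sign of
    the ratio conveys direction and is reported separately.
    """
    return float((2.0 ** abs(mean_log2_ratio) - 1.0) * 100.0)


def sensitivity_comparison(
    te_ribo: pd.Series,
    te_trap: pd.Series,
    high: float = TE_HIGH,
    low: float = TE_LOW,
) -> pd.DataFrame:
    """Ribosome-profiling vs TRAP sensitivity per TE category.

    Genes are categorized by the average of the two TE estimates; per
    category the mean log2(te_ribo / te_trap) is reported together with its
    percent-sensitivity conversion and the direction of the difference.
    Genes with a nonpositive TE in either method are excluded (logged).
    """
    both = pd.DataFrame({"ribo": te_ribo, "trap": te_trap}).dropna()
    bad = both.index[(both["ribo"] <= 0) | (both["trap"] <= 0)]
    if len(bad):
        logger.info("sensitivity_comparison: excluding %d genes with TE <= 0", len(bad))
        both = both.drop(bad)
    avg = (both["ribo"] + both["trap"]) / 2.0
    category = classify_te(avg, high=high, low=low)
    log2_ratio = np.log2(both["ribo"] / both["trap"])
    rows = []
    for cat in CATEGORIES:
        vals = log2_ratio[category == cat]
        if len(vals):
            m = float(vals.mean())
            rows.append(
                (cat, len(vals), m, percent_sensitivity(m),
                 "ribo_higher" if m > 0 else ("ribo_lower" if m < 0 else "equal"))
            )
        else:
            rows.append((cat, 0, np.nan, np.nan, "n/a"))
    return pd.DataFrame(
        rows, columns=["category", "n_genes", "mean_log2_ratio",
                       "percent_sensitivity", "direction"]
    ).set_index("category")


def _anchor_position(row: pd.Series, anchor: str) -> int:
    if anchor == "start_codon":
        return int(row["utr5_len"])
    if anchor == "stop_codon":
        return int(row["utr5_len"]) + int(row["cds_len"])
    raise ValueError(f"unknown anchor {anchor!r}")


def metagene_profile(
    fragments: pd.DataFrame,
    annotation: pd.DataFrame,
    anchor: str,
    window: tuple[int, int] = (50, 100),
    min_reads: int = 10,
) -> MetageneProfile:
    """Mean normalized per-base coverage around the start or stop codon.

    For each qualifying gene (>= ``min_reads`` fragments and an analysis
    window fully inside the transcript) per-base coverage over the window is
    divided by the gene's mean coverage over the window, then averaged across
    genes — so every gene contributes on the same scale regardless of its
    expression level.
    """
    upstream, downstream = window
    if upstream <= 0 or downstream <= 0:
        raise ValueError("window must be positive in both directions")
    offsets = np.arange(-upstream, downstream + 1)
    width = offsets.size

    unknown = set(fragments["transcript_id"].unique()) - set(annotation.index)
    if unknown:
        raise UnknownGeneError(sorted(unknown))

    total = np.zeros(width)
    n_genes = 0
    tlen = annotation[["utr5_len", "cds_len", "utr3_len"]].sum(axis=1)
    for gene_id, sub in fragments.groupby("transcript_id", sort=True):
        if len(sub) < min_reads:
            continue
        row = annotation.loc[gene_id]
        pos = _anchor_position(row, anchor)
        lo, hi = pos - upstream, pos + downstream + 1
        if lo < 0 or hi > int(tlen.loc[gene_id]):
            continue
        start = np.clip(sub["start"].to_numpy() - lo, 0, width)
        end = np.clip(sub["end"].to_numpy() - lo, 0, width)
        delta = np.zeros(width + 1)
        np.add.at(delta, start, 1.0)
        np.add.at(delta, end, -1.0)
        coverage = np.cumsum(delta[:-1])
        mean_cov = coverage.mean()
        if mean_cov == 0:
            continue
        total += coverage / mean_cov
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no genes qualify for the metagene profile")
    return MetageneProfile(
        anchor=anchor, offsets=offsets, density=total / n_genes, n_genes=n_genes
    )


def rank_te_extremes(
    te_mean: pd.Series, k: int = 100
) -> tuple[list[str], list[str]]:
    """The k genes with the lowest and the highest TE.

    Sorted by TE with ties broken by gene id (lexicographic), so the
    selection is stable across runs.  With fewer than k genes a warning is
    issued and all genes are returned.
    """
    frame = te_mean.rename("te").rename_axis("gene_id").reset_index()
    if len(frame) < k:
        warnings.warn(f"only {len(frame)} genes available; returning all")
        k = len(frame)
    asc = frame.sort_values(["te", "gene_id"], ascending=[True, True])
    desc = frame.sort_values(["te", "gene_id"], ascending=[False, True])
    return list(asc["gene_id"].head(k)), list(desc["gene_id"].head(k))
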