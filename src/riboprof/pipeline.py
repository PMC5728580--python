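"""End-to-end pipeline: simulate -> quantify -> TE -> metagene -> differential.

A :class:`PipelineConfig` (loadable from YAML) fixes the seed, thresholds and
genotypes; :func:`run_pipeline` executes the stages, writes TSV outputs plus
a JSON run manifest, and is byte-reproducible for a given config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, quantify, stats, te
from .simulate import (
    ASSAYS,
    ConfigurationError,
    GenotypeSpec,
    SimConfig,
    TEMixture,
    apply_genotype,
    generate_transcriptome,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    min_reads: int = 10
    te_high: float = 2.0
    te_low: float = 0.5
    te_fold_min: float = 2.0
    fold_min: float = 3.0
    alpha: float = 0.05

    def validate(self) -> None:
        if min(self.min_reads, self.te_high, self.te_low, self.fold_min,
               self.te_fold_min, self.alpha) <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.te_low >= self.te_high:
            raise ConfigurationError("te_low must be < te_high")


@dataclass
class PipelineConfig:
    """Run configuration: seed, simulation conditions, genotypes, thresholds."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    genotypes: list[GenotypeSpec] = field(
        default_factory=lambda: [GenotypeSpec(name="wt")]
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    log_transform: bool = True
    adjust: str = "none"
    metagene_window: tuple[int, int] = (50, 100)
    assays: tuple[str, ...] = ASSAYS

    def validate(self) -> None:
        self.thresholds.validate()
        self.sim.validate()
        if not self.genotypes:
            raise ConfigurationError("at least one genotype (the reference) required")
        names = [g.name for g in self.genotypes]
        if len(set(names)) != len(names):
            raise ConfigurationError("genotype names must be unique")
        if self.adjust not in ("none", "bh"):
            raise ConfigurationError("adjust must be 'none' or 'bh'")
        for assay in self.assays:
            if assay not in ASSAYS:
                raise ConfigurationError(f"unknown assay {assay!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim_data = dict(data.pop("sim", {}))
        if "te_mixture" in sim_data:
            sim_data["te_mixture"] = TEMixture(**sim_data["te_mixture"])
        if "footprint_len_range" in sim_data:
            sim_data["footprint_len_range"] = tuple(sim_data["footprint_len_range"])
        for key in ("utr5_range", "cds_codons_range", "utr3_range"):
            if key in sim_data:
                sim_data[key] = tuple(sim_data[key])
        sim = SimConfig(**sim_data)
        genotypes = [
            _genotype_from_dict(g) for g in data.pop("genotypes", [{"name": "wt"}])
        ]
        thresholds = Thresholds(**data.pop("thresholds", {}))
        if "metagene_window" in data:
            data["metagene_window"] = tuple(data["metagene_window"])
        if "assays" in data:
            data["assays"] = tuple(data["assays"])
        config = cls(sim=sim, genotypes=genotypes, thresholds=thresholds, **data)
        if "seed" not in sim_data:
            config.sim.seed = config.seed
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["genotypes"] = [_genotype_to_dict(g) for g in self.genotypes]
        return data


def _genotype_from_dict(data: dict) -> GenotypeSpec:
    data = dict(data)
    for key, width in (("deletions", 2), ("residual_fragments", 4),
                       ("transgene_variants", 5)):
        if key in data:
            fixed = []
            for item in data[key]:
                item = list(item)
                if key in ("deletions", "residual_fragments"):
                    item[1] = tuple(item[1])
                fixed.append(tuple(item))
            data[key] = fixed
    if "boosted_te_genes" in data:
        data["boosted_te_genes"] = frozenset(data["boosted_te_genes"])
    return GenotypeSpec(**data)


def _genotype_to_dict(genotype: GenotypeSpec) -> dict:
    data = dataclasses.asdict(genotype)
    data["boosted_te_genes"] = sorted(genotype.boosted_te_genes)
    return data


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write outputs plus a run manifest.

    Returns the manifest dictionary.  Stage outputs (all TSV, tab-separated
    with header):  transcripts.fasta, annotation.tsv, fragments_<g>.tsv,
    counts_<g>.tsv / totals_<g>.tsv / rpkm_<g>.tsv, te_<g>.tsv,
    metagene_<g>_<anchor>.tsv, and for every non-reference genotype
    diff_<g>_transcription.tsv, diff_<g>_translation.tsv,
    te_regulation_<g>.tsv, global_shift_<g>.tsv.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": [],
    }

    def _emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    # --- simulate -----------------------------------------------------------
    transcripts = generate_transcriptome(config.sim)
    annotation = quantify.annotation_frame(transcripts)
    for genotype in config.genotypes:
        extra = quantify.annotation_frame(
            apply_genotype(transcripts, genotype, seed=config.sim.seed)
        )
        annotation = pd.concat([annotation, extra.loc[~extra.index.isin(annotation.index)]])
    io.write_fasta(transcripts, _emit("transcripts.fasta"))
    io.write_annotation(annotation, _emit("annotation.tsv"))
    manifest["stages"]["simulate"] = {"n_genes": len(transcripts)}

    fragments: dict[str, pd.DataFrame] = {}
    for genotype in config.genotypes:
        frames = [
            simulate_reads(transcripts, genotype, config.sim, assay)
            for assay in config.assays
        ]
        frame = pd.concat(frames, ignore_index=True)
        fragments[genotype.name] = frame
        io.write_fragments(frame, _emit(f"fragments_{genotype.name}.tsv"))
        manifest["stages"]["simulate"][f"fragments_{genotype.name}"] = len(frame)
        logger.info("simulated %d fragments for %s", len(frame), genotype.name)

    # --- quantify -----------------------------------------------------------
    counts: dict[str, quantify.CountTable] = {}
    expr: dict[str, quantify.ExpressionTable] = {}
    gene_sets: dict[str, dict[str, set[str]]] = {}
    lengths = quantify.exon_lengths(annotation)
    for name, frame in fragments.items():
        table = quantify.count_reads(frame, annotation, genotype=name)
        counts[name] = table
        expr[name] = quantify.compute_rpkm(table, lengths)
        gene_sets[name] = quantify.expressed_gene_sets(
            table, config.thresholds.min_reads
        )
        io.write_count_table(table, _emit(f"counts_{name}.tsv"),
                             _emit(f"totals_{name}.tsv"))
        io.write_expression_table(expr[name], _emit(f"rpkm_{name}.tsv"))
        manifest["stages"].setdefault("quantify", {})[name] = {
            assay: len(genes) for assay, genes in gene_sets[name].items()
        }

    # --- TE -----------------------------------------------------------------
    te_tables: dict[str, pd.DataFrame] = {}
    for name in fragments:
        sets = gene_sets[name]
        # genes detected only transcriptionally are excluded from joint analyses
        joint = sets.get("total_rna", set()) & sets.get("footprint", set())
        if not joint:
            continue
        table = te.te_table(
            expr[name], genes=joint,
            high=config.thresholds.te_high, low=config.thresholds.te_low,
        )
        te_tables[name] = table
        io.write_table(table, _emit(f"te_{name}.tsv"))
        manifest["stages"].setdefault("te", {})[name] = {
            "n_genes": len(table),
            "categories": table["category"].value_counts().to_dict(),
        }

    # --- metagene -----------------------------------------------------------
    for name, frame in fragments.items():
        foot = frame[frame["assay"] == "footprint"]
        if not len(foot):
            continue
        for anchor in ("start_codon", "stop_codon"):
            try:
                profile = te.metagene_profile(
                    foot, annotation, anchor,
                    window=config.metagene_window,
                    min_reads=config.thresholds.min_reads,
                )
            except ValueError:
                continue
            table = pd.DataFrame(
                {"offset": profile.offsets, "density": profile.density,
                 "n_genes": profile.n_genes}
            )
            io.write_table(table, _emit(f"metagene_{name}_{anchor}.tsv"),
                           index=False)

    # --- differential -------------------------------------------------------
    reference = config.genotypes[0].name
    for genotype in config.genotypes[1:]:
        name = genotype.name
        diff_stage: dict = {}
        ribo_diff = None
        for assay, label in (("total_rna", "transcription"),
                             ("footprint", "translation")):
            if assay not in config.assays:
                continue
            genes = sorted(
                gene_sets[name].get(assay, set()) & gene_sets[reference].get(assay, set())
            )
            if not genes:
                continue
            table = stats.differential_table(
                counts[name], counts[reference], assay, genes=genes,
                fold_min=config.thresholds.fold_min,
                alpha=config.thresholds.alpha, adjust=config.adjust,
            )
            io.write_table(table, _emit(f"diff_{name}_{label}.tsv"))
            diff_stage[label] = table["call"].value_counts().to_dict()
            if label == "translation":
                ribo_diff = table

        joint_case = set(te_tables.get(name, pd.DataFrame()).index)
        joint_ref = set(te_tables.get(reference, pd.DataFrame()).index)
        joint = sorted(joint_case & joint_ref)
        if joint and ribo_diff is not None:
            reg = stats.translational_regulation_table(
                te.per_replicate_te(expr[name], genes=joint),
                te.per_replicate_te(expr[reference], genes=joint),
                ribo_diff,
                te_fold_min=config.thresholds.te_fold_min,
                alpha=config.thresholds.alpha,
            )
            io.write_table(reg, _emit(f"te_regulation_{name}.tsv"))
            diff_stage["translational_regulation"] = int(
                reg["translational_regulation"].sum()
            )

        if "footprint" in config.assays:
            shift = global_shift_analysis(
                counts[name], counts[reference], lengths, config,
                genes=sorted(
                    gene_sets[name].get("footprint", set())
                    & gene_sets[reference].get("footprint", set())
                ),
            )
            if shift is not None:
                io.write_table(shift.fc_histogram,
                               _emit(f"global_shift_{name}.tsv"), index=False)
                diff_stage["global_shift"] = {
                    "mean_fc": shift.mean_fc, "null_mean_fc": shift.null_mean_fc,
                    "ks_D": shift.ks_D, "ks_p": shift.ks_p,
                }
        manifest["stages"].setdefault("diff", {})[name] = diff_stage

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
    return manifest


def depth_calibrated_expression(
    table: quantify.CountTable,
    exon_len: pd.Series,
    library_size: float,
    assay: str,
    genes=None,
) -> pd.DataFrame:
    """Per-gene, per-replicate expression normalized to a nominal library size.

    Used for absolute between-library comparisons (global-shift analysis),
    where per-million normalization by realized totals would absorb a uniform
    genome-wide change.  Assumes libraries were depth-calibrated to the same
    input material, as the simulator's yield model guarantees.
    """
    nominal = pd.Series(
        {col: library_size for col in table.counts[assay].columns}
    )
    sub = quantify.CountTable(
        counts=pd.concat({assay: table.counts[assay]}, axis=1),
        total_mapped=pd.concat({assay: nominal}),
    )
    expr = quantify.compute_rpkm(sub, exon_len, total_mapped=sub.total_mapped)
    frame = expr.rpkm[assay]
    if genes is not None:
        frame = frame.loc[sorted(genes)]
    return frame


def global_shift_analysis(
    case: quantify.CountTable,
    control: quantify.CountTable,
    exon_len: pd.Series,
    config: PipelineConfig,
    genes,
    assay: str = "footprint",
) -> stats.GlobalShiftResult | None:
    """Global translation-shift analysis between two genotypes.

    Expression is depth-calibrated (nominal library size) so uniform shifts
    remain visible; the null distribution is the control's replicate split.
    """
    if not genes:
        return None
    library_size = config.sim.library_size[assay]
    expr_case = depth_calibrated_expression(case, exon_len, library_size, assay, genes)
    expr_ctrl = depth_calibrated_expression(control, exon_len, library_size, assay, genes)
    if expr_case.shape[1] != expr_ctrl.shape[1] or expr_ctrl.shape[1] < 2:
        return None
    null_case, null_ctrl = stats.replicate_split_null(expr_ctrl)
    return stats.global_shift(expr_case, expr_ctrl, null_case, null_ctrl)
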