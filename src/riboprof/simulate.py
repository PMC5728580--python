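"""Synthetic transcriptomes and reads for the three profiling assays.

This module generates the inputs the analysis stages expect: a transcriptome
with known ("true") transcription levels, translation efficiencies and
ribosome pause profiles; genotype perturbations (locus deletions with
residual fragments, transgenes with swapped UTRs, global or gene-set TE
multipliers); and seeded read sets for total-RNA, TRAP and ribosome-footprint
libraries.

Footprint reads emulate the experimental geometry: a ribosome position is
drawn over the 5'UTR+CDS weighted by the pause profile, a protected core is
extended outward to the nearest RNase-T1 cut site (cuts occur 3' of G
residues; transcript ends also terminate fragments), and only fragments whose
final length falls inside the gel size-selection window (30-45 nt by default)
are retained.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ASSAYS = ("total_rna", "trap", "footprint")

_BASES = np.array(list("ACGU"))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class UnknownGeneError(KeyError):
    """Raised when a genotype references gene ids absent from the transcriptome."""


@dataclass(eq=False)
class TranscriptModel:
    """One transcript with its structure, sequence and simulation truth.

    ``pause_profile`` is a per-position occupancy multiplier over the
    footprint-bearing span ``[0, utr5_len + cds_len)`` with mean 1; peaks mimic
    ribosome pause sites.  ``parent_id``/``parent_offset`` mark entries (e.g.
    residual fragments of a deleted locus) whose reads are reported in the
    coordinates of a parent transcript.
    """

    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: str
    true_transcription: float
    true_te: float
    pause_profile: np.ndarray
    te_class: str = "bulk"
    parent_id: str | None = None
    parent_offset: int = 0

    def __post_init__(self) -> None:
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError(f"{self.gene_id}: negative segment length")
        if self.cds_len < 3:
            raise ValueError(f"{self.gene_id}: cds_len must be >= 3")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"utr5+cds+utr3 = {self.length}"
            )
        if self.true_transcription < 0 or self.true_te < 0:
            raise ValueError(f"{self.gene_id}: negative expression truth")
        self.pause_profile = np.asarray(self.pause_profile, dtype=float)
        if self.pause_profile.shape != (self.utr5_len + self.cds_len,):
            raise ValueError(f"{self.gene_id}: pause_profile length mismatch")
        if self.pause_profile.size:
            if np.any(self.pause_profile <= 0):
                raise ValueError(f"{self.gene_id}: pause_profile must be > 0")
            if abs(self.pause_profile.mean() - 1.0) > 1e-9:
                raise ValueError(f"{self.gene_id}: pause_profile mean != 1")

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def footprint_span(self) -> int:
        """Length of the footprint-bearing 5'UTR+CDS span."""
        return self.utr5_len + self.cds_len

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptModel):
            return NotImplemented
        return (
            self.gene_id == other.gene_id
            and self.utr5_len == other.utr5_len
            and self.cds_len == other.cds_len
            and self.utr3_len == other.utr3_len
            and self.sequence == other.sequence
            and self.true_transcription == other.true_transcription
            and self.true_te == other.true_te
            and np.array_equal(self.pause_profile, other.pause_profile)
            and self.te_class == other.te_class
            and self.parent_id == other.parent_id
            and self.parent_offset == other.parent_offset
        )


@dataclass
class GenotypeSpec:
    """A genotype as a set of perturbations of the baseline transcriptome.

    ``deletions`` remove the intact mRNA of a locus (an interval record keeps
    the deleted span for bookkeeping); expression surviving a deletion must be
    declared explicitly as ``residual_fragments`` — sub-intervals transcribed
    on their own (e.g. from an adjacent promoter) with their own transcription
    and TE multipliers, whose reads are reported in parent coordinates.
    ``transgene_variants`` share the parent CDS but carry new UTRs.
    """

    name: str
    deletions: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    residual_fragments: list[tuple[str, tuple[int, int], float, float]] = field(
        default_factory=list
    )
    transgene_variants: list[tuple[str, int, int, float, float]] = field(
        default_factory=list
    )
    global_te_multiplier: float = 1.0
    boosted_te_genes: frozenset[str] = frozenset()
    boosted_te_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.global_te_multiplier < 0 or self.boosted_te_multiplier < 0:
            raise ConfigurationError("TE multipliers must be >= 0")
        for _, _, t_mult, te_mult in self.residual_fragments:
            if t_mult < 0 or te_mult < 0:
                raise ConfigurationError("residual multipliers must be >= 0")
        for _, _, _, t_mult, te_mult in self.transgene_variants:
            if t_mult < 0 or te_mult < 0:
                raise ConfigurationError("transgene multipliers must be >= 0")
        self.boosted_te_genes = frozenset(self.boosted_te_genes)

    @property
    def is_identity(self) -> bool:
        return (
            not self.deletions
            and not self.residual_fragments
            and not self.transgene_variants
            and self.global_te_multiplier == 1.0
            and (not self.boosted_te_genes or self.boosted_te_multiplier == 1.0)
        )


WILD_TYPE = GenotypeSpec(name="wt")


@dataclass
class TEMixture:
    """Log-normal TE distribution with an optional low-TE spike class.

    The spike emulates a coherently suppressed gene class (ribosomal-protein
    like, TE ~ 0.09).  When ``center`` is set, drawn TE values are rescaled so
    the transcription-weighted mean TE equals 1: the absolute TE scale is not
    identifiable from depth-normalized expression ratios, so centering puts
    the simulated truth on the same scale the estimator reports.
    """

    log_mean: float = 0.0
    log_sigma: float = 0.75
    low_fraction: float = 0.25
    low_log_mean: float = float(np.log(0.09))
    low_log_sigma: float = 0.25
    center: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.low_fraction <= 1.0:
            raise ConfigurationError("low_fraction must be in [0, 1]")
        if self.log_sigma < 0 or self.low_log_sigma < 0:
            raise ConfigurationError("log sigmas must be >= 0")

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Return (te, te_class) arrays of length ``n``."""
        is_low = rng.random(n) < self.low_fraction
        te = np.where(
            is_low,
            rng.lognormal(self.low_log_mean, self.low_log_sigma, n),
            rng.lognormal(self.log_mean, self.log_sigma, n),
        )
        te_class = np.where(is_low, "low_spike", "bulk")
        return te, te_class


@dataclass
class SimConfig:
    """Study conditions for the read simulator.

    ``dispersion`` is the negative-binomial dispersion alpha of between-
    replicate count noise (var = mu + alpha mu^2, i.e. the squared biological
    coefficient of variation).  ``library_size`` is the expected fragment
    yield per replicate for an unperturbed transcriptome; see
    :func:`simulate_reads` for how perturbed genotypes scale against it.
    """

    seed: int = 0
    n_genes: int = 300
    n_replicates: int = 3
    library_size: Mapping[str, int] = field(
        default_factory=lambda: {a: 200_000 for a in ASSAYS}
    )
    footprint_len_range: tuple[int, int] = (30, 45)
    protected_core_len: int = 30
    dispersion: float = 0.05
    te_mixture: TEMixture = field(default_factory=TEMixture)
    transcription_te_anticorrelation: bool = True
    transcription_log_mean: float = float(np.log(50.0))
    transcription_log_sigma: float = 1.0
    utr5_range: tuple[int, int] = (50, 300)
    cds_codons_range: tuple[int, int] = (100, 500)
    utr3_range: tuple[int, int] = (50, 300)
    mrna_read_len: int = 75
    pause_gamma_shape: float = 2.0
    pause_peak_prob: float = 0.005
    pause_peak_strength: float = 10.0
    cut_five_prime: bool = True

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        lo, hi = self.footprint_len_range
        if lo > hi or lo < 1:
            raise ConfigurationError("invalid footprint_len_range")
        if self.protected_core_len < 1:
            raise ConfigurationError("protected_core_len must be >= 1")
        for assay in ASSAYS:
            if assay not in self.library_size:
                raise ConfigurationError(f"library_size missing assay {assay!r}")
            if self.library_size[assay] <= 0:
                raise ConfigurationError("library sizes must be > 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        for name in ("utr5_range", "cds_codons_range", "utr3_range"):
            a, b = getattr(self, name)
            if a > b or a < 0:
                raise ConfigurationError(f"invalid {name}")
        if self.cds_codons_range[0] < 1:
            raise ConfigurationError("cds_codons_range must start at >= 1 codon")
        if self.mrna_read_len < 1:
            raise ConfigurationError("mrna_read_len must be >= 1")
        self.te_mixture.validate()


def generate_transcriptome(config: SimConfig) -> list[TranscriptModel]:
    """Draw a seeded transcriptome with the configured statistical structure.

    Sequences have uniform base composition (so RNase-T1 G cut sites are
    frequent), TE values come from ``config.te_mixture``, and when
    ``transcription_te_anticorrelation`` is on the rank correlation between
    transcription and TE is negative, as observed for real transcriptomes.
    Deterministic for a given seed.
    """
    config.validate()
    n = config.n_genes
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)

    utr5 = rng.integers(config.utr5_range[0], config.utr5_range[1] + 1, n)
    cds = 3 * rng.integers(config.cds_codons_range[0], config.cds_codons_range[1] + 1, n)
    utr3 = rng.integers(config.utr3_range[0], config.utr3_range[1] + 1, n)

    te, te_class = config.te_mixture.draw(n, rng)
    transcription = rng.lognormal(
        config.transcription_log_mean, config.transcription_log_sigma, n
    )
    if config.transcription_te_anticorrelation and n > 1:
        # Noisy anti-rank coupling: high-TE genes receive low transcription.
        ranks = np.argsort(np.argsort(te)) / (n - 1)
        score = -ranks + rng.normal(0.0, 0.35, n)
        coupled = np.empty(n)
        coupled[np.argsort(score)] = np.sort(transcription)
        transcription = coupled
    if config.te_mixture.center:
        weighted_mean = float((transcription * te).sum() / transcription.sum())
        if weighted_mean > 0:
            te = te / weighted_mean

    width = max(4, len(str(n)))
    transcripts = []
    for i in range(n):
        length = int(utr5[i] + cds[i] + utr3[i])
        seq = "".join(_BASES[rng.integers(0, 4, length)])
        span = int(utr5[i] + cds[i])
        profile = rng.gamma(
            config.pause_gamma_shape, 1.0 / config.pause_gamma_shape, span
        )
        peaks = rng.random(span) < config.pause_peak_prob
        profile[peaks] *= config.pause_peak_strength
        profile /= profile.mean()
        transcripts.append(
            TranscriptModel(
                gene_id=f"g{i:0{width}d}",
                utr5_len=int(utr5[i]),
                cds_len=int(cds[i]),
                utr3_len=int(utr3[i]),
                sequence=seq,
                true_transcription=float(transcription[i]),
                true_te=float(te[i]),
                pause_profile=profile,
                te_class=str(te_class[i]),
            )
        )
    return transcripts


def _base_id(gene_id: str) -> str:
    return gene_id.split("|", 1)[0]


def _sliced_profile(parent: TranscriptModel, start: int, end: int) -> np.ndarray:
    """Pause profile for a sub-interval, padding with 1 beyond the parent span."""
    span_end = min(end, parent.footprint_span)
    parts = []
    if start < span_end:
        parts.append(parent.pause_profile[start:span_end])
    if end > max(start, span_end):
        parts.append(np.ones(end - max(start, span_end)))
    profile = np.concatenate(parts) if parts else np.ones(0)
    if profile.size:
        profile = profile / profile.mean()
    return profile


def apply_genotype(
    transcripts: Sequence[TranscriptModel],
    genotype: GenotypeSpec,
    seed: int = 0,
) -> list[TranscriptModel]:
    """Return the transcript set a genotype actually expresses.

    A deletion removes the intact mRNA of its locus (no read mass anywhere on
    the original transcript); residual fragments and transgene variants are
    appended as new entries; the global and gene-set TE multipliers rescale
    every entry's TE.  ``seed`` only affects the random UTR sequences of
    transgene variants.
    """
    index = {t.gene_id: t for t in transcripts}
    referenced = (
        [g for g, _ in genotype.deletions]
        + [g for g, _, _, _ in genotype.residual_fragments]
        + [g for g, _, _, _, _ in genotype.transgene_variants]
    )
    unknown = sorted(set(referenced) - set(index))
    if unknown:
        raise UnknownGeneError(f"genotype {genotype.name!r}: unknown gene ids {unknown}")

    out = [
        replace(t, pause_profile=t.pause_profile.copy()) for t in transcripts
    ]
    by_id = {t.gene_id: t for t in out}
    rng = np.random.default_rng([seed, zlib.crc32(genotype.name.encode())])

    for gene_id, (start, end) in genotype.deletions:
        parent = index[gene_id]
        if not 0 <= start < end <= parent.length:
            raise ConfigurationError(
                f"deletion interval ({start}, {end}) outside {gene_id}"
            )
        by_id[gene_id].true_transcription = 0.0

    for gene_id, (start, end), t_mult, te_mult in genotype.residual_fragments:
        parent = index[gene_id]
        if not 0 <= start < end <= parent.length:
            raise ConfigurationError(
                f"residual interval ({start}, {end}) outside {gene_id}"
            )
        if end - start < 3:
            raise ConfigurationError("residual fragments must span >= 3 nt")
        out.append(
            TranscriptModel(
                gene_id=f"{gene_id}|res_{start}_{end}",
                utr5_len=0,
                cds_len=end - start,
                utr3_len=0,
                sequence=parent.sequence[start:end],
                true_transcription=parent.true_transcription * t_mult,
                true_te=parent.true_te * te_mult,
                pause_profile=_sliced_profile(parent, start, end),
                te_class=parent.te_class,
                parent_id=gene_id,
                parent_offset=start,
            )
        )

    for gene_id, new_utr5, new_utr3, t_mult, te_mult in genotype.transgene_variants:
        parent = index[gene_id]
        if new_utr5 < 0 or new_utr3 < 0:
            raise ConfigurationError("transgene UTR lengths must be >= 0")
        cds_seq = parent.sequence[parent.utr5_len : parent.utr5_len + parent.cds_len]
        utr5_seq = "".join(_BASES[rng.integers(0, 4, new_utr5)])
        utr3_seq = "".join(_BASES[rng.integers(0, 4, new_utr3)])
        cds_prof = parent.pause_profile[parent.utr5_len : parent.footprint_span]
        profile = np.concatenate([np.ones(new_utr5), cds_prof])
        profile /= profile.mean()
        out.append(
            TranscriptModel(
                gene_id=f"{gene_id}|tg",
                utr5_len=new_utr5,
                cds_len=parent.cds_len,
                utr3_len=new_utr3,
                sequence=utr5_seq + cds_seq + utr3_seq,
                true_transcription=parent.true_transcription * t_mult,
                true_te=parent.true_te * te_mult,
                pause_profile=profile,
                te_class=parent.te_class,
            )
        )

    if genotype.global_te_multiplier != 1.0:
        for t in out:
            t.true_te *= genotype.global_te_multiplier
    if genotype.boosted_te_genes and genotype.boosted_te_multiplier != 1.0:
        for t in out:
            if _base_id(t.gene_id) in genotype.boosted_te_genes or (
                t.parent_id is not None and _base_id(t.parent_id) in genotype.boosted_te_genes
            ):
                t.true_te *= genotype.boosted_te_multiplier
    return out


def _cut_boundaries(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position nearest RNase-T1 cut boundaries.

    A boundary exists at position i iff i is a transcript end or the residue
    at i-1 is G (the enzyme cuts 3' of G).  Returns (prev_cut, next_cut)
    arrays over positions 0..L such that prev_cut[x] is the largest boundary
    <= x and next_cut[x] the smallest boundary >= x.
    """
    length = len(sequence)
    arr = np.frombuffer(sequence.encode("ascii"), dtype="S1")
    boundary = np.zeros(length + 1, dtype=bool)
    boundary[0] = boundary[length] = True
    if length > 1:
        boundary[1:length] = arr[: length - 1] == b"G"
    idx = np.arange(length + 1)
    prev_cut = np.maximum.accumulate(np.where(boundary, idx, 0))
    next_cut = np.minimum.accumulate(np.where(boundary, idx, length)[::-1])[::-1]
    return prev_cut, next_cut


def _assay_weight(t: TranscriptModel, assay: str) -> float:
    if assay == "total_rna":
        return t.true_transcription
    return t.true_transcription * t.true_te


def _replicate_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, dispersion * means)
    else:
        lam = means
    return rng.poisson(lam)


def simulate_reads(
    transcripts: Sequence[TranscriptModel],
    genotype: GenotypeSpec | None,
    config: SimConfig,
    assay: str,
) -> pd.DataFrame:
    """Simulate one assay's fragment set for every replicate of a genotype.

    Per-gene replicate counts follow a Poisson-gamma (negative binomial) model
    with mean proportional to transcription (total_rna) or transcription x TE
    (trap, footprint).  Expected yields are calibrated against the unperturbed
    transcriptome's total transcription, so genotype-wide perturbations (e.g.
    a global TE multiplier) change absolute yields the way they would change
    the amount of ribosome-protected material.

    Returns a fragment table with columns transcript_id, start, end, assay,
    replicate, genotype (0-based half-open transcript coordinates).
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    config.validate()
    genotype = genotype or WILD_TYPE
    effective = apply_genotype(transcripts, genotype, seed=config.seed)

    empty = pd.DataFrame(
        {
            "transcript_id": pd.Series([], dtype=object),
            "start": pd.Series([], dtype=np.int64),
            "end": pd.Series([], dtype=np.int64),
            "assay": pd.Series([], dtype=object),
            "replicate": pd.Series([], dtype=np.int64),
            "genotype": pd.Series([], dtype=object),
        }
    )
    if not effective:
        return empty

    # Depth calibration: the unperturbed transcriptome at TE scale 1 defines
    # the expected library yield; perturbed weights scale against it.
    baseline = sum(_assay_weight(t, "total_rna") for t in transcripts)
    if baseline <= 0:
        return empty
    weights = np.array([_assay_weight(t, assay) for t in effective])
    means = config.library_size[assay] * weights / baseline

    rng = np.random.default_rng(
        [config.seed, ASSAYS.index(assay), zlib.crc32(genotype.name.encode())]
    )

    lo, hi = config.footprint_len_range
    core = config.protected_core_len
    half = core // 2
    prepared = []
    for t in effective:
        if assay == "footprint":
            span = t.footprint_span
            prob = t.pause_profile / t.pause_profile.sum() if span else None
            prev_cut, next_cut = _cut_boundaries(t.sequence)
            prepared.append((t, prob, prev_cut, next_cut))
        else:
            prepared.append((t, None, None, None))

    tids: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    reps: list[np.ndarray] = []
    for rep in range(config.n_replicates):
        counts = _replicate_counts(rng, means, config.dispersion)
        for (t, prob, prev_cut, next_cut), k in zip(prepared, counts):
            if k == 0:
                continue
            length = t.length
            if assay == "footprint":
                if t.footprint_span == 0:
                    continue
                pos = rng.choice(t.footprint_span, size=k, p=prob)
                core_start = np.clip(pos - half, 0, length)
                core_end = np.clip(pos - half + core, 0, length)
                start = prev_cut[core_start] if config.cut_five_prime else core_start
                end = next_cut[core_end]
                frag_len = end - start
                keep = (frag_len >= lo) & (frag_len <= hi)
                start, end = start[keep], end[keep]
            else:
                read_len = min(config.mrna_read_len, length)
                start = rng.integers(0, length - read_len + 1, size=k)
                end = start + read_len
            if start.size == 0:
                continue
            if t.parent_id is not None:
                tid = t.parent_id
                start = start + t.parent_offset
                end = end + t.parent_offset
            else:
                tid = t.gene_id
            tids.append(np.full(start.size, tid, dtype=object))
            starts.append(start.astype(np.int64))
            ends.append(end.astype(np.int64))
            reps.append(np.full(start.size, rep, dtype=np.int64))

    if not tids:
        return empty
    frame = pd.DataFrame(
        {
            "transcript_id": np.concatenate(tids),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
            "assay": assay,
            "replicate": np.concatenate(reps),
            "genotype": genotype.name,
        }
    )
    return frame


def simulate_experiment(
    transcripts: Sequence[TranscriptModel],
    genotype: GenotypeSpec | None,
    config: SimConfig,
    assays: Sequence[str] = ASSAYS,
) -> pd.DataFrame:
    """Concatenated fragment table over several assays for one genotype."""
    frames = [simulate_reads(transcripts, genotype, config, a) for a in assays]
    return pd.concat(frames, ignore_index=True)
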