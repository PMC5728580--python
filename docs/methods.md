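# Methods

This note documents the models behind `riboprof`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All intervals are 0-based, half-open, on transcript coordinates. Fragments
are carried as a pandas DataFrame (`transcript_id, start, end, assay,
replicate, genotype`); a `FragmentRecord` dataclass and converters are
provided for record-level work. Counts and RPKM live in gene × (assay,
replicate) DataFrames inside `CountTable` / `ExpressionTable`.

## The read simulator

### Transcriptome

Each gene has a 5'UTR, CDS (multiple of 3) and 3'UTR with lengths drawn
uniformly from configurable ranges (defaults 50–300, 300–1500, 50–300 nt —
compact metazoan mRNAs), a uniform-composition {A,C,G,U} sequence (so RNase
T1 cut sites occur every ~4 nt), a log-normal transcription level (σ = 1, a
typical bulk RNA-seq abundance spread), and a translation efficiency drawn
from a mixture: a log-normal bulk (σ = 0.75 in natural log, wide enough to
populate the TE > 2 and TE < 0.5 classes) plus a low-TE spike (25% of genes,
log-mean ln 0.09) emulating a coherently suppressed class such as ribosomal
proteins. When `transcription_te_anticorrelation` is on (default), TE ranks
are coupled to transcription ranks with noise so high-TE genes tend to be
transcribed at low levels, the inverse trend seen in real TE landscapes.

**TE centering.** The absolute TE scale is not identifiable from
depth-normalized expression ratios: estimated TE equals true TE only up to
the factor Σt/Σ(t·TE). Drawn TE values are therefore rescaled once so the
transcription-weighted mean TE is 1, putting the simulation truth on the
same scale the estimator reports. A degenerate mixture with all TE = 1 is
preserved exactly.

A per-position pause profile over the 5'UTR+CDS (i.i.d. Gamma(2) values,
rare strong peaks: probability 0.005/nt of a ×10 multiplier, renormalized to
mean 1) gives footprint coverage the irregular peaked structure of ribosome
pause sites.

### Read generation

Per gene, per replicate, fragment counts are Poisson-Gamma (negative
binomial): mean `μ_g = library_size · w_g / W₀` and variance `μ + α μ²`,
where `w_g` is `t_g` (total RNA) or `t_g·TE_g` (TRAP, footprint) and the
dispersion α (default 0.05, a typical between-replicate biological CV² for
bulk RNA-seq) is shared across genes. **Depth calibration:** the normalizer
`W₀` is the summed transcription of the *unperturbed* transcriptome, i.e.
`library_size` is the expected yield of a wild-type library and perturbed
genotypes scale against it — a genotype with globally elevated ribosome
loading yields proportionally more footprint material. Under strict
per-million renormalization a uniform genome-wide shift is mathematically
invisible; this yield model is what makes the global-shift analysis (below)
a solvable problem, and corresponds to libraries prepared from equal tissue
input.

Total-RNA and TRAP fragments are 75 nt (single-end read length), positioned
uniformly over the transcript. Footprints: a ribosome position is drawn over
the 5'UTR+CDS weighted by the pause profile (footprints populate the 5'UTR
and CDS and avoid the 3'UTR); a 30-nt protected core centered on that
position is extended outward on each side to the nearest RNase-T1 cut
boundary (cuts strictly 3' of G; transcript ends also terminate fragments);
the fragment is kept only if its final length lies in the 30–45 nt gel
window. Failed fragments are discarded, not re-drawn, so per-gene yields
remain sequence-dependent as in a real digest. The 5'-end cut requirement is
configurable (`cut_five_prime`); both ends are cut by default.

With a centered core, a footprint whose core ends just past the stop codon
plus a 3' G-extension can overhang the CDS end by up to
`(core − core//2 − 1) + (window_max − core)` nt (29 with defaults); the
property suite asserts this geometric bound and, more importantly, that
under defaults < 1% of footprint base-mass falls in 3'UTRs.

### Genotypes

A `GenotypeSpec` perturbs the baseline: **deletions** remove the intact mRNA
of a locus (a 5'-deleted gene produces no full-length transcript); any
surviving expression is declared explicitly as **residual fragments** —
sub-intervals transcribed on their own (e.g. from an adjacent promoter) with
their own transcription/TE multipliers, whose reads are emitted in parent
coordinates so locus-level region analyses work unchanged. **Transgene
variants** share the parent CDS with new random UTRs and their own
multipliers and appear as separate transcript entries. A global TE
multiplier rescales every gene; a boosted gene set (TOP-mRNA-like) gets an
extra TE multiplier.

### What the simulator does not emulate

No genome coordinates, splicing, multi-mapping, sequencing errors, quality
scores or FASTQ; no codon-level periodicity or P-site geometry; TRAP is
simulated with the same mean structure as footprints (full-length coverage,
TE-weighted abundance), so the simulated ribo-vs-TRAP sensitivity comparison
is null by construction — the percent-sensitivity conversion is validated as
an analytic transform, and the TRAP compression seen in real data is not
modeled. Passing tests therefore demonstrate correctness of the quantification
and statistics under the stated noise model, not robustness to alignment
artifacts or library-chemistry biases.

## Quantification

Counting assigns each fragment to exactly one gene by transcript id;
`total_mapped` per assay/replicate is the number of fragments processed.
RPKM uses per-replicate totals (replicates are sequenced separately). The
expression filter requires ≥ `min_reads` (default 10) in **every** replicate
of an assay; the threshold is the depth below which replicate variability
rises sharply, and "≥ 10 in all replicates" is the strict reading adopted
here (configurable). Genes detected only in total RNA are excluded from
joint analyses.

Region analyses sum per-base coverage mass inside each interval. The
region-partition expression of a case library relative to a reference is
`(case density / case library size) ÷ (reference density / reference library
size)`; a reference region with no mass reports NaN. Replicate agreement is
the squared Pearson correlation of log10 RPKM (log scale by default, as
replicate scatter is assessed on log axes).

## TE analysis

Per-gene TE uses replicate-**mean** RPKM in numerator and denominator (the
stable choice; per-replicate TEs are also emitted for replicate-level
tests). Boundaries 2 and 0.5 are exclusive for high/low: the boundaries
belong to medium. The sensitivity comparison categorizes genes by the
*average* of the two methods' TEs, reports the per-category mean
log2(TE_ribo/TE_TRAP) and converts its magnitude to percent as
`(2^|m| − 1)·100`, the direction reported separately.

Metagene profiles: per qualifying gene (≥ `min_reads` fragments, analysis
window fully inside the transcript), window coverage is normalized by the
gene's mean coverage over the window before averaging across genes — each
gene contributes equally regardless of expression. Ranking of TE extremes
breaks ties lexicographically by gene id so selections are stable.

## Differential statistics

The weighted t-type test is a proportion-based random-effects model: within-
replicate binomial variance `p̂(1−p̂)/n_i` plus a shared between-replicate
component τ² estimated by the method of moments (DerSimonian–Laird form,
clamped at 0), with weight/estimate updates iterated to convergence
(tolerance 1e-10, max 50 iterations; a floor of `0.5/Σn` keeps the binomial
variance positive at p̂ ∈ {0,1}). Degrees of freedom are Welch–Satterthwaite
with K−1 per group. When τ̂² = 0 the statistic reduces to the fixed-effect
inverse-binomial-variance form. Two behaviors worth knowing:

- **Low-count conservatism.** When binomial noise dominates the biological
  dispersion (roughly, counts below ~1/α), τ̂² clamps to zero most of the
  time and an essentially known-variance statistic is referred to a
  t-distribution with ~4 df, so the test rejects *less* than nominal — never
  more. Calibration is therefore assessed (tests and acceptance script) at a
  well-expressed-gene regime (mean proportion 5e-3 at depth 2e5, ~1000
  counts/replicate, dispersion 0.01) where the between-replicate component
  is identifiable.
- **Dispersion parameterization.** One number is used across the package:
  the negative-binomial α (variance = μ + αμ², the squared biological CV).
  The beta-binomial calibration generator maps it to Var(p_i) = α·p₀².

The TE test is a two-sample Student t on per-replicate log2 TE (variance
stabilization for ratios; a raw-scale option exists). Translational
regulation requires TE fold ≥ 2 with p < 0.05 *and* a significant footprint
expression change in the increasing direction — the two criteria exclude
apparent TE changes that are transcriptionally driven. Differential calls
use raw p < 0.05 by default, matching the primary calling rule;
Benjamini–Hochberg adjustment is available behind `adjust="bh"`.

### Global shift

Per-gene fold changes are **pooled index-paired replicate ratios**
(case rep i / control rep i), and the intrinsic-variability null is the
control paired with its own cyclically rotated replicates. This pairing was
chosen deliberately: the null ratios then have the same single-replicate
marginal distribution as a case-vs-control ratio under no effect, so the
two-sample KS test compares like with like (a 3v3 mean-ratio case against a
1v1 split null would differ in spread even under the null and flag shifts
that do not exist; the cyclic null's within-gene dependence is negatively
correlated, which is conservative). `mean_fc` is the arithmetic mean of the
pooled ratios; note E[x/y] = FC·(1+CV²) for ratio data, so with default
noise a true 1.6× shift reads out near 1.7 and the no-change null reads near
1.07 — the analysis is used for distribution shifts, not as an unbiased FC
estimator. A geometric-mean option is provided and labeled. Expression for
this analysis is normalized to the **nominal** library size (depth
calibration, see the simulator): realized-total normalization would absorb a
uniform shift.

## Problem sizes

Simulated checks are sized for a single CPU: TE recovery and footprint
geometry on 300 genes at 2e5 fragments/library; test calibration on 2000
beta-binomial genes; the global shift on 2000 genes; the translational-
regulation null on 10 runs of a **50-gene** transcriptome at default depth —
50 genes keeps the per-gene read depth (~4000 reads/gene) at the level of a
deep sequencing study, which is the regime the 2-fold + dual-significance
gates are designed for; at 10× shallower per-gene depth the gates sit at ~2σ
of TE noise and occasional false calls are intrinsic rather than a
calibration defect.

## Known limitations

- The weighted test is conservative at low counts (see above); this is the
  safe direction and one more reason for the ≥ 10-read filter.
- TE category accuracy near the 0.5 / 2 boundaries is limited by sampling
  noise; accuracy guarantees are only meaningful away from the boundaries.
- The simulator's depth-calibration assumption (equal tissue input per
  library) is what licenses absolute fold-change recovery; with real data
  normalized per million mapped reads, only non-uniform shifts are
  detectable and the global-shift mean must be interpreted accordingly.
- Fragment-to-gene assignment is by transcript id; multi-isoform and
  multi-mapping resolution are upstream problems out of scope.
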