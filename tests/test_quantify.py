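import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riboprof as rp
from riboprof.quantify import CountTable, gene_regions

from conftest import brute_force_counts, make_fragments


class TestCountReads:
    def test_direct_count(self, toy_annotation):
        rows = [("geneA", 0, 50, "total_rna", 0)] * 7 + [
            ("geneB", 10, 60, "total_rna", 0)
        ] * 3
        table = rp.count_reads(make_fragments(rows), toy_annotation)
        assert table.counts.loc["geneA", ("total_rna", 0)] == 7
        assert table.counts.loc["geneB", ("total_rna", 0)] == 3
        assert table.total_mapped[("total_rna", 0)] == 10

    def test_empty_input(self, toy_annotation):
        table = rp.count_reads(make_fragments([]), toy_annotation)
        assert table.counts.to_numpy().sum() == 0
        assert table.total_mapped.sum() == 0

    def test_unknown_transcript_listed(self, toy_annotation):
        frags = make_fragments([("geneZ", 0, 10, "total_rna", 0)])
        with pytest.raises(rp.UnknownGeneError, match="geneZ"):
            rp.count_reads(frags, toy_annotation)

    def test_out_of_bounds_rejected(self, toy_annotation):
        frags = make_fragments([("geneB", 200, 260, "total_rna", 0)])
        with pytest.raises(ValueError, match="bounds"):
            rp.count_reads(frags, toy_annotation)

    def test_matches_bruteforce_tally_on_simulated_reads(
        self, small_transcriptome, small_annotation, small_config
    ):
        frags = rp.simulate_experiment(small_transcriptome, None, small_config)
        table = rp.count_reads(frags, small_annotation)
        oracle = brute_force_counts(frags)
        for (gene, assay, rep), expected in oracle.items():
            assert table.counts.loc[gene, (assay, rep)] == expected
        assert table.counts.to_numpy().sum() == sum(oracle.values())

    def test_conservation_column_sums_equal_totals(
        self, small_transcriptome, small_annotation, small_config
    ):
        frags = rp.simulate_experiment(small_transcriptome, None, small_config)
        table = rp.count_reads(frags, small_annotation)
        for col in table.counts.columns:
            assert table.counts[col].sum() == table.total_mapped[col]


class TestFilterExpressed:
    @staticmethod
    def _table(counts):
        frame = pd.DataFrame(
            {("footprint", i): [c] for i, c in enumerate(counts)},
            index=pd.Index(["g"], name="gene_id"),
        )
        frame.columns.names = ["assay", "replicate"]
        totals = pd.Series(
            {("footprint", i): 1000 for i in range(len(counts))}
        )
        return CountTable(frame, totals)

    def test_boundary_inclusive(self):
        assert rp.filter_expressed(self._table([10, 12, 15]), "footprint") == {"g"}

    def test_one_replicate_below_threshold_fails(self):
        assert rp.filter_expressed(self._table([9, 50, 50]), "footprint") == set()

    def test_all_zero_empty(self):
        assert rp.filter_expressed(self._table([0, 0, 0]), "footprint") == set()

    def test_monotone_in_min_reads(self, small_transcriptome, small_annotation, small_config):
        frags = rp.simulate_experiment(small_transcriptome, None, small_config)
        table = rp.count_reads(frags, small_annotation)
        previous = rp.filter_expressed(table, "footprint", 1)
        for threshold in (5, 10, 50, 200):
            current = rp.filter_expressed(table, "footprint", threshold)
            assert current <= previous
            previous = current


class TestComputeRpkm:
    def test_unit_case(self, toy_annotation):
        rows = [("geneA", 0, 50, "total_rna", 0)]
        table = rp.count_reads(make_fragments(rows), toy_annotation)
        table.counts.loc["geneA", ("total_rna", 0)] = 1000
        table.total_mapped[("total_rna", 0)] = 10**6
        exon_len = pd.Series({"geneA": 1000, "geneB": 1000})
        expr = rp.compute_rpkm(table, exon_len)
        assert expr.rpkm.loc["geneA", ("total_rna", 0)] == pytest.approx(1000.0)
        assert expr.rpkm.loc["geneB", ("total_rna", 0)] == 0.0

    def test_formula_oracle(self, small_transcriptome, small_annotation, small_config):
        frags = rp.simulate_experiment(small_transcriptome, None, small_config)
        table = rp.count_reads(frags, small_annotation)
        exon_len = rp.exon_lengths(small_annotation)
        expr = rp.compute_rpkm(table, exon_len)
        for gene in small_annotation.index[:5]:
            for col in table.counts.columns:
                expected = table.counts.loc[gene, col] / (
                    (exon_len[gene] / 1e3) * (table.total_mapped[col] / 1e6)
                )
                assert expr.rpkm.loc[gene, col] == pytest.approx(expected, rel=1e-9)

    def test_scaling_invariance(self, toy_annotation):
        rows = [("geneA", 0, 50, "total_rna", 0)] * 4 + [("geneB", 0, 10, "total_rna", 0)]
        table = rp.count_reads(make_fragments(rows), toy_annotation)
        exon_len = rp.exon_lengths(toy_annotation)
        doubled = CountTable(table.counts * 2, table.total_mapped * 2)
        pd.testing.assert_frame_equal(
            rp.compute_rpkm(table, exon_len).rpkm,
            rp.compute_rpkm(doubled, exon_len).rpkm,
        )

    def test_zero_total_mapped_error(self, toy_annotation):
        table = rp.count_reads(
            make_fragments([("geneA", 0, 5, "total_rna", 0)]), toy_annotation
        )
        table.total_mapped[("total_rna", 0)] = 0
        with pytest.raises(ValueError):
            rp.compute_rpkm(table, rp.exon_lengths(toy_annotation))


class TestRegionCoverage:
    def test_fragment_inside_cds(self, toy_annotation):
        frags = make_fragments([("geneA", 150, 200, "footprint", 0)])
        assert rp.region_coverage_fractions(frags, toy_annotation, "geneA") == (0, 1, 0)

    def test_fragment_straddling_boundary(self, toy_annotation):
        frags = make_fragments([("geneA", 80, 120, "footprint", 0)])
        u5, cds, u3 = rp.region_coverage_fractions(frags, toy_annotation, "geneA")
        assert (u5, cds, u3) == (0.5, 0.5, 0.0)

    def test_zero_coverage_flagged(self, toy_annotation):
        with pytest.warns(UserWarning, match="zero coverage"):
            out = rp.region_coverage_fractions(
                make_fragments([]), toy_annotation, "geneA"
            )
        assert all(np.isnan(v) for v in out)

    def test_fractions_sum_to_one(self, small_transcriptome, small_annotation, small_config):
        frags = rp.simulate_reads(small_transcriptome, None, small_config, "footprint")
        for gene in small_annotation.index[:5]:
            if (frags["transcript_id"] == gene).any():
                fracs = rp.region_coverage_fractions(frags, small_annotation, gene)
                assert sum(fracs) == pytest.approx(1.0, abs=1e-9)


class TestRegionPartitionExpression:
    def test_reference_vs_itself_is_one(self, toy_annotation):
        frags = make_fragments(
            [("geneA", 0, 60, "total_rna", 0), ("geneA", 200, 260, "total_rna", 0)]
        )
        regions = gene_regions(toy_annotation, "geneA")
        out = rp.region_partition_expression(frags, frags, regions, 100.0, 100.0)
        assert out.values["utr5"] == pytest.approx(1.0)
        assert out.values["cds"] == pytest.approx(1.0)

    def test_library_size_normalization(self, toy_annotation):
        ref = make_fragments([("geneA", 150, 200, "total_rna", 0)])
        case = make_fragments([("geneA", 150, 200, "total_rna", 0)] * 2)
        regions = gene_regions(toy_annotation, "geneA")
        out = rp.region_partition_expression(case, ref, regions, 200.0, 100.0)
        assert out.values["cds"] == pytest.approx(1.0)

    def test_empty_reference_region_undefined(self, toy_annotation):
        ref = make_fragments([("geneA", 150, 200, "total_rna", 0)])
        case = make_fragments([("geneA", 0, 50, "total_rna", 0)])
        regions = gene_regions(toy_annotation, "geneA")
        out = rp.region_partition_expression(case, ref, regions, 1.0, 1.0)
        assert np.isnan(out.values["utr5"])
        assert out.values["cds"] == 0.0


class TestReplicateCorrelation:
    @staticmethod
    def _expr(x, y):
        genes = pd.Index([f"g{i}" for i in range(len(x))], name="gene_id")
        rpkm = pd.DataFrame(
            {("total_rna", 0): x, ("total_rna", 1): y}, index=genes
        )
        rpkm.columns.names = ["assay", "replicate"]
        return rp.ExpressionTable(
            rpkm=rpkm,
            exon_len=pd.Series(1000.0, index=genes),
            total_mapped=pd.Series({("total_rna", 0): 1e6, ("total_rna", 1): 1e6}),
        )

    def test_identical_replicates(self):
        x = np.array([1.0, 5.0, 20.0, 80.0])
        assert rp.replicate_correlation(self._expr(x, x), "total_rna", 0, 1) == pytest.approx(1.0)

    def test_scaled_replicate_still_perfect(self):
        x = np.array([1.0, 5.0, 20.0, 80.0])
        expr = self._expr(x, 2 * x)
        assert rp.replicate_correlation(expr, "total_rna", 0, 1) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(12)
        expr = self._expr(rng.lognormal(0, 1, 1000), rng.lognormal(0, 1, 1000))
        assert rp.replicate_correlation(expr, "total_rna", 0, 1) < 0.05

    def test_too_few_genes(self):
        expr = self._expr(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            rp.replicate_correlation(expr, "total_rna", 0, 1)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 1000), min_size=2, max_size=6),
    scale=st.integers(2, 10),
)
def test_rpkm_scale_invariance_property(counts, scale):
    """Multiplying every count and total by the same factor leaves RPKM fixed."""
    genes = pd.Index([f"g{i}" for i in range(len(counts))], name="gene_id")
    frame = pd.DataFrame({("total_rna", 0): counts}, index=genes)
    frame.columns.names = ["assay", "replicate"]
    total = max(sum(counts), 1)
    exon_len = pd.Series(500.0, index=genes)
    base = rp.compute_rpkm(
        CountTable(frame, pd.Series({("total_rna", 0): total})), exon_len
    ).rpkm
    scaled = rp.compute_rpkm(
        CountTable(frame * scale, pd.Series({("total_rna", 0): total * scale})),
        exon_len,
    ).rpkm
    assert np.allclose(base.to_numpy(), scaled.to_numpy())
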