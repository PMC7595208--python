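import numpy as np
import pandas as pd
import pytest

from altprom.genemodel import (
    Annotation,
    AnnotationRow,
    GenomicInterval,
    SpliceJunction,
)
from altprom.quant import (
    FilterConfig,
    WindowSpec,
    aggregate,
    count_window,
    extended_exon_window,
    filter_dataset,
    filter_gene,
    normalize_jpm,
)

from conftest import make_matrix

GENE = GenomicInterval("chr18", 52_889_562, 53_332_018, "-")


class TestFilterDataset:
    def test_support_threshold_is_at_least(self):
        m = make_matrix(
            [
                ("chr18", 0, 100, "-", "CT/AC", [3, 3]),   # sum 6: kept
                ("chr18", 0, 200, "-", "CT/AC", [3, 2]),   # sum 5: removed
            ],
            ["a", "b"],
        )
        out = filter_dataset(m, FilterConfig())
        assert list(out.counts.index) == ["chr18:0-100:-"]

    def test_mitochondrial_removed_regardless_of_support(self):
        m = make_matrix(
            [("chrM", 0, 100, "+", "GT/AG", [100])], ["a"]
        )
        assert filter_dataset(m, FilterConfig()).n_junctions == 0

    def test_non_canonical_removed(self):
        m = make_matrix(
            [("chr18", 0, 100, "-", "non-canonical", [50])], ["a"]
        )
        assert filter_dataset(m, FilterConfig()).n_junctions == 0

    def test_identity_configuration(self):
        m = make_matrix(
            [
                ("chrM", 0, 100, "+", "GT/AG", [1]),
                ("chr18", 0, 100, "-", "non-canonical", [0]),
            ],
            ["a"],
        )
        cfg = FilterConfig(
            min_dataset_reads_genomewide=0,
            min_dataset_reads_gene=0,
            exclude_chroms=frozenset(),
            canonical_only=False,
        )
        out = filter_dataset(m, cfg)
        pd.testing.assert_frame_equal(out.counts, m.counts)


class TestFilterGene:
    def test_in_gene_floor(self):
        m = make_matrix(
            [
                ("chr18", 53_000_000, 53_000_100, "-", "CT/AC", [2, 1]),  # 3: out
                ("chr18", 53_000_000, 53_000_200, "-", "CT/AC", [2, 2]),  # 4: kept
            ],
            ["a", "b"],
        )
        out = filter_gene(m, GENE, min_reads=4)
        assert list(out.counts.index) == ["chr18:53000000-53000200:-"]

    def test_outside_gene_untouched(self):
        m = make_matrix([("chr2", 0, 100, "+", "GT/AG", [1])], ["a"])
        out = filter_gene(m, GENE, min_reads=4)
        assert out.n_junctions == 1

    def test_empty_matrix(self):
        m = make_matrix([("chr18", 53_000_000, 53_000_100, "-", "CT/AC", [1])], ["a"])
        empty = m.subset([])
        assert filter_gene(empty, GENE).n_junctions == 0

    def test_filters_idempotent(self):
        rng = np.random.default_rng(3)
        from conftest import random_small_matrix

        for _ in range(20):
            m = random_small_matrix(rng)
            cfg = FilterConfig()
            once = filter_gene(filter_dataset(m, cfg), GENE)
            twice = filter_gene(filter_dataset(once, cfg), GENE)
            pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestNormalizeJpm:
    def test_definition(self):
        m = make_matrix(
            [
                ("chr18", 0, 100, "-", "CT/AC", [5, 0]),
                ("chr18", 0, 200, "-", "CT/AC", [15, 10]),
            ],
            ["a", "b"],
        )
        jpm = normalize_jpm(m)
        assert jpm.loc["chr18:0-100:-", "a"] == pytest.approx(5 / 20 * 1e6)
        assert jpm.loc["chr18:0-100:-", "b"] == 0.0

    def test_self_normalization(self):
        m = make_matrix([("chr18", 0, 100, "-", "CT/AC", [10])], ["a"])
        assert normalize_jpm(m).iloc[0, 0] == pytest.approx(1_000_000.0)

    def test_conservation(self):
        rng = np.random.default_rng(5)
        from conftest import random_small_matrix

        for _ in range(20):
            m = random_small_matrix(rng)
            totals = m.sample_totals()
            m = m.subset(m.counts.index[m.row_sums() >= 0])
            if (totals == 0).any():
                continue
            sums = normalize_jpm(m).sum(axis=0)
            assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_zero_total_names_sample(self):
        m = make_matrix([("chr18", 0, 100, "-", "CT/AC", [0, 5])], ["empty", "ok"])
        with pytest.raises(ValueError, match="empty"):
            normalize_jpm(m)

    def test_external_totals(self):
        m = make_matrix([("chr18", 0, 100, "-", "CT/AC", [5])], ["a"])
        jpm = normalize_jpm(m, totals=pd.Series({"a": 1_000_000}))
        assert jpm.iloc[0, 0] == pytest.approx(5.0)


class TestCountWindow:
    SPEC = WindowSpec(GenomicInterval("chr18", 53_251_150, 53_251_152, "-"), "4")

    def test_spanning_block_counted(self):
        w = self.SPEC.window
        reads = [[(w.start - 10, w.end + 10)]]
        assert count_window(reads, self.SPEC) == 1

    def test_spliced_gap_not_counted(self):
        w = self.SPEC.window
        reads = [[(w.start - 30, w.start), (w.end, w.end + 30)]]
        assert count_window(reads, self.SPEC) == 0

    def test_partial_coverage_not_counted(self):
        w = self.SPEC.window
        assert count_window([[(w.start - 5, w.start + 1)]], self.SPEC) == 0
        assert count_window([[(w.start + 1, w.end + 5)]], self.SPEC) == 0

    def test_exact_window_block_counted(self):
        w = self.SPEC.window
        assert count_window([[(w.start, w.end)]], self.SPEC) == 1

    def test_matches_per_position_coverage_oracle(self):
        rng = np.random.default_rng(11)
        w = self.SPEC.window
        reads = []
        for _ in range(200):
            a = int(rng.integers(w.start - 20, w.end + 20))
            b = a + int(rng.integers(1, 40))
            if rng.random() < 0.4:  # spliced read: two blocks with a gap
                gap_at = a + int(rng.integers(1, b - a)) if b - a > 1 else a + 1
                reads.append([(a, gap_at), (gap_at + 5, b + 10)])
            else:
                reads.append([(a, b)])
        # oracle: enumerate the positions of each block and ask whether a
        # single block's position set contains both window bases
        window_positions = {w.start, w.start + 1}
        expected = sum(
            any(window_positions <= set(range(s, e)) for s, e in blocks)
            for blocks in reads
        )
        assert count_window(reads, self.SPEC) == expected

    def test_chrom_aware_blocks(self):
        w = self.SPEC.window
        reads = [[("chr1", w.start - 10, w.end + 10)]]
        assert count_window(reads, self.SPEC) == 0

    def test_window_orientation_minus_strand(self, demo_gene):
        spec = extended_exon_window(demo_gene, "4")
        exon = demo_gene.internal_exons["4"]
        assert (spec.window.start, spec.window.end) == (exon.end, exon.end + 2)

    def test_window_must_be_two_bp(self):
        with pytest.raises(ValueError):
            WindowSpec(GenomicInterval("chr1", 0, 3), "4")


def _ann(rows):
    return Annotation(
        [
            AnnotationRow(
                SpliceJunction("chr18", start, end, "-", "CT/AC"), event, iso
            )
            for start, end, event, iso in rows
        ]
    )


class TestAggregate:
    def test_event_summation(self):
        ann = _ann([(0, 100, "3b-4", "TCF4-C"), (0, 200, "3b-4", "TCF4-C")])
        expr = pd.DataFrame(
            {"s": [2.0, 3.0]},
            index=["chr18:0-100:-", "chr18:0-200:-"],
        )
        out = aggregate(expr, ann, by="event")
        assert out.loc["3b-4", "s"] == pytest.approx(5.0)

    def test_empty_annotation(self):
        expr = pd.DataFrame({"s": [1.0]}, index=["chr18:0-100:-"])
        out = aggregate(expr, Annotation([]), by="event")
        assert out.empty

    def test_isoform_grouping(self):
        ann = _ann(
            [
                (0, 100, "3b-3", "TCF4-B"),
                (0, 200, "3c-3", "TCF4-B"),
                (0, 300, "3d-3", "TCF4-B"),
                (0, 400, "6-7", "none"),
            ]
        )
        expr = pd.DataFrame(
            {"s": [1.0, 2.0, 4.0, 100.0]},
            index=[f"chr18:0-{e}:-" for e in (100, 200, 300, 400)],
        )
        out = aggregate(expr, ann, by="isoform")
        assert list(out.index) == ["TCF4-B"]
        assert out.loc["TCF4-B", "s"] == pytest.approx(7.0)

    def test_window_rows_join_events(self):
        ann = _ann([(0, 100, "4aI-4", "TCF4-E")])
        expr = pd.DataFrame(
            {"s": [1.5, 2.5]}, index=["chr18:0-100:-", "4c"]
        )
        out = aggregate(expr, ann, by="event", window_events={"4c": "other"})
        assert out.loc["4c", "s"] == pytest.approx(2.5)
        iso = aggregate(expr, ann, by="isoform", window_events={"4c": "other"})
        assert iso.loc["other", "s"] == pytest.approx(2.5)

    def test_unannotated_rows_dropped(self):
        ann = _ann([(0, 100, "3b-4", "TCF4-C")])
        expr = pd.DataFrame(
            {"s": [1.0, 9.0]}, index=["chr18:0-100:-", "chr18:0-999:-"]
        )
        out = aggregate(expr, ann, by="event")
        assert list(out.index) == ["3b-4"]

    def test_linearity(self):
        rng = np.random.default_rng(9)
        ann = _ann(
            [(0, 100, "3b-4", "TCF4-C"), (0, 200, "3b-4", "TCF4-C"),
             (0, 300, "6-7", "none")]
        )
        idx = ["chr18:0-100:-", "chr18:0-200:-", "chr18:0-300:-"]
        a = pd.DataFrame(rng.random((3, 2)), index=idx, columns=["x", "y"])
        b = pd.DataFrame(rng.random((3, 2)), index=idx, columns=["x", "y"])
        left = aggregate(a + b, ann, by="event")
        right = aggregate(a, ann, by="event") + aggregate(b, ann, by="event")
        pd.testing.assert_frame_equal(left, right)
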