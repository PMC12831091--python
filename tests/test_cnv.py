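import numpy as np
import pytest

from myelotriage.cnv import (
    CNVSegment,
    DepthBin,
    basepair_concordance,
    bins_to_copynumber,
    filter_segments,
    genes_affected,
    read_depth_bins,
    segment_copynumber,
    write_depth_bins,
)
from myelotriage.genomic import GenomicInterval, GeneTarget, TriageThresholds


def make_bins(depths, contig="chr1", size=100_000, start=0):
    return [
        DepthBin(GenomicInterval(contig, start + i * size, start + (i + 1) * size), d)
        for i, d in enumerate(depths)
    ]


def seg(contig, start, end, state, cn):
    return CNVSegment(GenomicInterval(contig, start, end), state, cn)


class TestBinsToCopynumber:
    def test_uniform_depth_is_diploid(self):
        cn = bins_to_copynumber(make_bins([30.0] * 10))
        assert all(c == pytest.approx(2.0) for _, c in cn)

    def test_half_depth_is_single_copy(self):
        cn = bins_to_copynumber(make_bins([30.0] * 9 + [15.0]))
        assert cn[-1][1] == pytest.approx(1.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(2)
        depths = rng.uniform(5, 80, size=200)
        cn = bins_to_copynumber(make_bins(list(depths)))
        median = np.median(depths)
        for (_, got), d in zip(cn, depths):
            assert got == pytest.approx(2 * d / median)

    def test_sex_contigs_excluded_from_median(self):
        auto = make_bins([30.0] * 5, contig="chr1")
        x = make_bins([15.0] * 50, contig="chrX")
        cn = dict(
            (b.interval.contig, c) for b, c in bins_to_copynumber(auto + x)
        )
        assert cn["chr1"] == pytest.approx(2.0)  # median from autosomes only
        assert cn["chrX"] == pytest.approx(1.0)

    def test_all_zero_depth_errors(self):
        with pytest.raises(ValueError):
            bins_to_copynumber(make_bins([0.0] * 5))


class TestSegmentation:
    def test_run_of_low_bins_is_one_loss_segment(self, thresholds):
        cn = [(b, 1.2) for b in make_bins([18.0] * 5)]
        segments = segment_copynumber(cn, thresholds)
        assert len(segments) == 1
        assert segments[0].state == "loss"
        assert len(segments[0].interval) == 500_000
        assert segments[0].mean_cn == pytest.approx(1.2)

    def test_cn_between_cutoffs_yields_no_segment(self, thresholds):
        cn = [(b, 1.8) for b in make_bins([27.0])]
        assert segment_copynumber(cn, thresholds) == []

    def test_alternating_bins_make_single_bin_segments(self, thresholds):
        cns = [1.0, 2.0] * 5
        cn = list(zip(make_bins([15.0] * 10), cns))
        segments = segment_copynumber(cn, thresholds)
        assert len(segments) == 5
        assert all(len(s.interval) == 100_000 and s.state == "loss" for s in segments)

    def test_coordinate_gap_breaks_run(self, thresholds):
        bins = make_bins([15.0] * 2) + make_bins([15.0] * 2, start=400_000)
        cn = [(b, 1.0) for b in bins]
        segments = segment_copynumber(cn, thresholds)
        assert len(segments) == 2  # no gap bridging

    def test_matches_run_length_oracle(self, thresholds):
        rng = np.random.default_rng(9)
        for _ in range(200):
            values = rng.choice([0.8, 1.5, 1.9, 2.0, 2.2, 2.6, 3.1],
                                size=rng.integers(1, 40))
            cn = list(zip(make_bins([30.0] * len(values)), values))
            segments = segment_copynumber(cn, thresholds)
            # brute-force: label each bin, then group consecutive labels
            labels = [
                "loss" if v < 1.7 else "gain" if v > 2.3 else None for v in values
            ]
            expected = []
            i = 0
            while i < len(labels):
                if labels[i] is None:
                    i += 1
                    continue
                j = i
                while j + 1 < len(labels) and labels[j + 1] == labels[i]:
                    j += 1
                expected.append((i, j + 1, labels[i], np.mean(values[i:j + 1])))
                i = j + 1
            assert len(segments) == len(expected)
            for s, (i0, i1, state, mean_cn) in zip(segments, expected):
                assert s.interval.start == i0 * 100_000
                assert s.interval.end == i1 * 100_000
                assert s.state == state
                assert s.mean_cn == pytest.approx(mean_cn)

    def test_sex_contig_haploid_expectation(self, thresholds):
        bins = make_bins([30.0] * 4, contig="chrX")
        cn = [(b, 1.0) for b in bins]  # normal male X
        assert segment_copynumber(cn, thresholds) == []
        assert segment_copynumber(cn, thresholds, include_sex=True) == []
        lost = [(b, 0.4) for b in bins]
        out = segment_copynumber(lost, thresholds, include_sex=True)
        assert len(out) == 1 and out[0].state == "loss"


class TestFilterSegments:
    def test_strict_threshold(self):
        exactly = seg("chr1", 0, 300_000, "loss", 1.0)
        longer = seg("chr1", 0, 301_000, "loss", 1.0)
        assert filter_segments([exactly, longer], 300_000) == [longer]

    def test_empty(self):
        assert filter_segments([], 300_000) == []


class TestBasepairConcordance:
    def test_identical_sets(self):
        a = [seg("chr1", 0, 1000, "loss", 1.0)]
        assert basepair_concordance(a, a, "loss") == pytest.approx(1.0)

    def test_disjoint_sets(self):
        a = [seg("chr1", 0, 1000, "loss", 1.0)]
        b = [seg("chr1", 5000, 6000, "loss", 1.0)]
        assert basepair_concordance(a, b, "loss") == pytest.approx(0.0)

    def test_half_overlap(self):
        a = [seg("chr1", 0, 1000, "loss", 1.0)]
        b = [seg("chr1", 500, 1500, "loss", 1.0)]
        assert basepair_concordance(a, b, "loss") == pytest.approx(0.5)

    def test_empty_a_is_undefined(self):
        assert basepair_concordance([], [seg("chr1", 0, 10, "loss", 1)], "loss") is None

    def test_mixed_states_rejected(self):
        a = [seg("chr1", 0, 1000, "gain", 3.0)]
        with pytest.raises(ValueError):
            basepair_concordance(a, a, "loss")

    def test_matches_base_counting_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            def random_set():
                out = []
                for _ in range(rng.integers(1, 5)):
                    s = int(rng.integers(0, 5_000))
                    out.append(seg("chr1", s, s + int(rng.integers(1, 2_000)),
                                   "loss", 1.0))
                return out
            a, b = random_set(), random_set()
            a_bases = set()
            for s in a:
                a_bases |= set(range(s.interval.start, s.interval.end))
            b_bases = set()
            for s in b:
                b_bases |= set(range(s.interval.start, s.interval.end))
            expected = len(a_bases & b_bases) / len(a_bases)
            assert basepair_concordance(a, b, "loss") == pytest.approx(expected)


class TestGenesAffected:
    def test_overlap_semantics(self, toy_panel):
        spanning = seg("chr1", 90_000, 120_000, "loss", 1.0)
        before_gene = seg("chr1", 400_000, 500_000, "gain", 3.0)  # ends at start
        affected = genes_affected([spanning, before_gene], toy_panel)
        assert affected["loss"] == {"GENE_A"}
        assert affected["gain"] == set()  # half-open: no overlap at the boundary

    def test_matches_per_base_intersection(self, toy_panel):
        rng = np.random.default_rng(4)
        for _ in range(100):
            s = int(rng.integers(0, 600_000))
            segment = seg("chr1" if rng.random() < 0.7 else "chr2",
                          s, s + int(rng.integers(1, 100_000)),
                          "loss" if rng.random() < 0.5 else "gain", 1.0)
            got = genes_affected([segment], toy_panel)
            for gene in toy_panel.with_role("CNV"):
                overlap = any(
                    iv.contig == segment.interval.contig
                    and set(range(iv.start, iv.end))
                    & set(range(segment.interval.start, segment.interval.end))
                    for iv in gene.intervals
                )
                assert (gene.symbol in got[segment.state]) is overlap


class TestParameterRecovery:
    def test_planted_deletion_recovered_within_one_bin(self, thresholds):
        """A clonal 10-Mbp deletion at 60x must segment to +-1 bin of truth."""
        rng = np.random.default_rng(17)
        bin_size, contig_len = 100_000, 30_000_000
        del_start, del_end = 8_000_000, 18_000_000
        bins = []
        for start in range(0, contig_len, bin_size):
            deleted = del_start <= start < del_end
            expected_depth = 30.0 if deleted else 60.0
            # ~600 independent read draws per bin at 60x with 10-kbp reads
            n_reads = rng.poisson(expected_depth * bin_size / 10_000)
            bins.append(
                DepthBin(
                    GenomicInterval("chr1", start, start + bin_size),
                    n_reads * 10_000 / bin_size,
                )
            )
        segments = filter_segments(
            segment_copynumber(bins_to_copynumber(bins), thresholds),
            thresholds.min_cnv_reportable,
        )
        assert len(segments) == 1
        assert segments[0].state == "loss"
        assert abs(segments[0].interval.start - del_start) <= bin_size
        assert abs(segments[0].interval.end - del_end) <= bin_size


def test_depth_bin_io_roundtrip(tmp_path):
    bins = make_bins([30.0, 28.5, 61.25])
    path = tmp_path / "bins.tsv"
    write_depth_bins(bins, path)
    back = read_depth_bins(path)
    assert [b.interval for b in back] == [b.interval for b in bins]
    assert [b.depth for b in back] == pytest.approx([b.depth for b in bins])
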