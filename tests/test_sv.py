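import numpy as np
import pytest

from myelotriage.genomic import (
    GenePanel,
    GenomicInterval,
    GeneTarget,
    RecurrentPair,
    TriageThresholds,
)
from myelotriage.sv import (
    Breakend,
    KnownInsertion,
    SVCall,
    classify_recurrent,
    filter_reportable_sv,
    insertion_proximity_filter,
    read_sv_vcf,
    subtract_population,
    write_sv_vcf,
)


@pytest.fixture
def sv_panel():
    """GENE_A/GENE_B are reported genes; FUS1/FUS2 are fusion partners."""
    return GenePanel(
        [
            GeneTarget("GENE_A", (GenomicInterval("chr1", 100_000, 130_000),),
                       roles=frozenset({"small-variant", "CNV"})),
            GeneTarget("GENE_B", (GenomicInterval("chr2", 100_000, 130_000),),
                       roles=frozenset({"small-variant", "CNV"})),
            GeneTarget("FUS1", (GenomicInterval("chr1", 500_000, 530_000),),
                       roles=frozenset({"SV-partner"})),
            GeneTarget("FUS2", (GenomicInterval("chr2", 500_000, 530_000),),
                       roles=frozenset({"SV-partner"})),
        ]
    )


def make_del(start=125_000, svlen=8_000, contig="chr1", support=5,
             abundance=0.2, **kw):
    defaults = dict(
        svtype="DEL",
        end1=Breakend(contig, start),
        end2=Breakend(contig, start + svlen, "-"),
        svlen=svlen, support=support, abundance=abundance,
        consequence="frameshift",
    )
    defaults.update(kw)
    return SVCall(**defaults)


def make_bnd(c1, p1, c2, p2, **kw):
    defaults = dict(
        svtype="BND", end1=Breakend(c1, p1, "+"), end2=Breakend(c2, p2, "-"),
        support=10, abundance=0.3,
    )
    defaults.update(kw)
    return SVCall(**defaults)


class TestFilterReportableSV:
    def test_reportable_deletion_kept(self, sv_panel):
        # 8 kbp DEL, 5 reads, 20% abundance, 3 kbp upstream of GENE_A
        call = make_del(start=89_000)
        assert filter_reportable_sv([call], sv_panel) == [call]

    def test_bnd_too_far_from_partner_genes_removed(self, sv_panel):
        # one end 25 kbp past FUS1's end, other end intergenic
        call = make_bnd("chr1", 530_000 + 25_000, "chr3", 1_000_000)
        assert filter_reportable_sv([call], sv_panel) == []

    def test_bnd_near_partner_gene_kept(self, sv_panel):
        call = make_bnd("chr1", 510_000, "chr3", 1_000_000)
        assert filter_reportable_sv([call], sv_panel) == [call]

    def test_low_support_removed(self, sv_panel):
        call = make_del(svtype="DUP", support=1)
        assert filter_reportable_sv([call], sv_panel) == []

    @pytest.mark.parametrize(
        "kw",
        [
            {"abundance": 0.05},          # must be strictly > 5%
            {"svlen": 4_000},             # below 5 kbp reportable floor
            {"filter_status": "LowQual"},
            {"consequence": "intron_variant"},
            {"start": 160_000},           # > 20 kbp from GENE_A
        ],
    )
    def test_each_rule_removes(self, sv_panel, kw):
        assert filter_reportable_sv([make_del(**kw)], sv_panel) == []

    def test_missing_svlen_on_length_type_errors(self, sv_panel):
        call = SVCall(svtype="INS", end1=Breakend("chr1", 110_000),
                      support=5, abundance=0.2)
        with pytest.raises(ValueError, match="svlen"):
            filter_reportable_sv([call], sv_panel)

    def test_idempotent(self, sv_panel):
        calls = [make_del(), make_del(start=89_000),
                 make_bnd("chr1", 510_000, "chr2", 510_000)]
        once = filter_reportable_sv(calls, sv_panel)
        assert filter_reportable_sv(once, sv_panel) == once


class TestSubtractPopulation:
    def test_identical_coordinates_removed(self):
        call = make_del()
        assert subtract_population([call], [make_del()]) == []

    def test_beyond_match_distance_kept(self):
        call = make_del(start=125_500)
        assert subtract_population([call], [make_del(start=125_000)]) == [call]

    def test_size_ratio_required(self):
        call = make_del(svlen=8_000)
        near_same_start = SVCall(
            svtype="DEL", end1=Breakend("chr1", 125_000),
            end2=Breakend("chr1", 125_000 + 5_000, "-"), svlen=5_000,
            support=10, abundance=0.5,
        )
        # second breakend 3 kbp apart anyway, but test ratio logic directly
        assert subtract_population([call], [near_same_start]) == [call]

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(13)
        def random_call():
            start = int(rng.integers(1, 500_000))
            svlen = int(rng.integers(100, 20_000))
            return make_del(start=start, svlen=svlen)
        calls = [random_call() for _ in range(120)]
        known = [random_call() for _ in range(120)]
        got = subtract_population(calls, known)
        expected = []
        for c in calls:
            matched = False
            for k in known:
                same_ends = (
                    abs(c.end1.position - k.end1.position) <= 100
                    and abs(c.end2.position - k.end2.position) <= 100
                ) or (
                    abs(c.end1.position - k.end2.position) <= 100
                    and abs(c.end2.position - k.end1.position) <= 100
                )
                ratio = min(c.svlen, k.svlen) / max(c.svlen, k.svlen)
                if same_ends and ratio >= 0.8:
                    matched = True
                    break
            if not matched:
                expected.append(c)
        assert got == expected

    def test_idempotent(self):
        calls = [make_del(start=s) for s in (10_000, 125_000, 300_000)]
        known = [make_del(start=125_050)]
        once = subtract_population(calls, known)
        assert subtract_population(once, known) == once


class TestClassifyRecurrent:
    PAIRS = [RecurrentPair("FUS1", "FUS2")]

    def test_both_ends_near_pair_members(self, sv_panel):
        call = make_bnd("chr1", 495_000, "chr2", 518_000)  # 5 kbp / inside
        assert classify_recurrent(call, self.PAIRS, sv_panel)

    def test_swapped_end_assignment(self, sv_panel):
        call = make_bnd("chr2", 510_000, "chr1", 510_000)
        assert classify_recurrent(call, self.PAIRS, sv_panel)

    def test_both_ends_near_same_gene_only(self, sv_panel):
        call = make_bnd("chr1", 505_000, "chr1", 525_000)
        assert not classify_recurrent(call, self.PAIRS, sv_panel)

    def test_unresolvable_pair_gene_errors(self, sv_panel):
        call = make_bnd("chr1", 510_000, "chr2", 510_000)
        with pytest.raises(ValueError, match="not resolvable"):
            classify_recurrent(call, [RecurrentPair("FUS1", "NOPE")], sv_panel)


class TestInsertionProximityFilter:
    INSERTIONS = [KnownInsertion(GenomicInterval("chr5", 99_999, 100_000))]

    def test_nonrecurrent_near_insertion_removed(self):
        call = make_bnd("chr5", 101_500, "chr9", 5_000_000)  # 1.5 kbp away
        assert insertion_proximity_filter([call], self.INSERTIONS) == []

    def test_recurrent_exempt(self):
        call = make_bnd("chr5", 101_500, "chr9", 5_000_000, recurrent=True)
        assert insertion_proximity_filter([call], self.INSERTIONS) == [call]

    def test_beyond_threshold_kept(self):
        call = make_bnd("chr5", 102_501, "chr9", 5_000_000)
        assert insertion_proximity_filter([call], self.INSERTIONS) == [call]

    def test_boundary_inclusive(self):
        call = make_bnd("chr5", 102_000, "chr9", 5_000_000)  # exactly 2 kbp
        assert insertion_proximity_filter([call], self.INSERTIONS) == []


class TestSVCallInvariants:
    def test_del_requires_ordered_same_contig_ends(self):
        with pytest.raises(ValueError):
            SVCall(svtype="DEL", end1=Breakend("chr1", 2000),
                   end2=Breakend("chr1", 1000, "-"), svlen=1000)
        with pytest.raises(ValueError):
            SVCall(svtype="DEL", end1=Breakend("chr1", 1000),
                   end2=Breakend("chr2", 2000, "-"), svlen=1000)

    def test_abundance_bounds(self):
        with pytest.raises(ValueError):
            make_del(abundance=1.5)


class TestSvVcfRoundtrip:
    def test_roundtrip_all_types(self, tmp_path):
        calls = [
            make_del(name="del1"),
            SVCall(svtype="DUP", end1=Breakend("chr1", 200_000),
                   end2=Breakend("chr1", 260_000, "-"), svlen=60_000,
                   support=8, abundance=0.4, name="dup1",
                   consequence="transcript_amplification"),
            SVCall(svtype="INS", end1=Breakend("chr2", 50_000), svlen=1_600,
                   support=12, abundance=0.5, name="ins1"),
            make_bnd("chr1", 510_000, "chr2", 510_000, recurrent=True,
                     name="bnd1", genes_hit=("FUS1", "FUS2")),
            make_bnd("chr2", 40_000, "chr1", 90_000, name="bnd2"),
        ]
        path = tmp_path / "svs.vcf"
        write_sv_vcf(calls, path, contigs={"chr1": 1_000_000, "chr2": 1_000_000})
        back = {c.name: c for c in read_sv_vcf(path)}
        assert set(back) == {"del1", "dup1", "ins1", "bnd1", "bnd2"}
        for orig in calls:
            got = back[orig.name]
            assert got.svtype == orig.svtype
            assert got.end1 == orig.end1
            assert got.end2 == orig.end2
            assert got.svlen == orig.svlen
            assert got.support == orig.support
            assert got.abundance == pytest.approx(orig.abundance, rel=1e-5)
            assert got.recurrent == orig.recurrent
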