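import pytest

from myelotriage.genomic import GenePanel, GenomicInterval, GeneTarget, TriageThresholds


@pytest.fixture
def thresholds():
    return TriageThresholds()


@pytest.fixture
def toy_panel():
    """Three genes on two contigs; GENE_C lacks the small-variant role."""
    return GenePanel(
        [
            GeneTarget(
                "GENE_A",
                (GenomicInterval("chr1", 100_000, 102_000),
                 GenomicInterval("chr1", 110_000, 112_000)),
            ),
            GeneTarget("GENE_B", (GenomicInterval("chr1", 500_000, 530_000),)),
            GeneTarget(
                "GENE_C",
                (GenomicInterval("chr2", 200_000, 240_000),),
                roles=frozenset({"CNV", "SV-partner"}),
            ),
        ]
    )
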