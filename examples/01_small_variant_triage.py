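"""Small-variant triage: caller union, reportability rules, indel filter.

Builds a toy pair of caller outputs for one tumor sample and walks them
through the reporting rules: union of primary PASS calls with secondary
PASS/NonSomatic calls, restriction to protein-altering consequences in
panel genes, the 0.1% population-frequency exclusion with hotspot
rescue, and the phase-aware both-haplotype indel filter.
"""

from myelotriage import (
    GenePanel,
    GeneTarget,
    GenomicInterval,
    SmallVariantCall,
    TriageThresholds,
    both_haplotype_indel_filter,
    filter_reportable,
    merge_callsets,
)

panel = GenePanel([
    GeneTarget("NRAS_LIKE", (GenomicInterval("chr1", 100_000, 130_000),)),
    GeneTarget("TET2_LIKE", (GenomicInterval("chr4", 500_000, 560_000),)),
])


def call(contig, pos, ref, alt, gene, csq, maf=None, status="PASS",
         hotspot=False, hap=(10, 10, 20, 0)):
    h1r, h1a, h2r, h2a = hap
    return SmallVariantCall(
        contig=contig, position=pos, ref=ref, alt=alt,
        total_depth=h1r + h1a + h2r + h2a, alt_depth=h1a + h2a,
        hap1_ref=h1r, hap1_alt=h1a, hap2_ref=h2r, hap2_alt=h2a,
        gene=gene, consequence=csq, max_population_maf=maf,
        filter_status=status, hotspot=hotspot,
    )


primary = [  # germline-style caller, PASS calls enter the union
    call("chr1", 115_000, "G", "A", "NRAS_LIKE", "missense_variant"),
    call("chr4", 520_000, "C", "T", "TET2_LIKE", "stop_gained"),
    call("chr4", 530_000, "A", "G", "TET2_LIKE", "intron_variant"),
]
secondary = [  # tumor-only caller: PASS and NonSomatic calls enter
    call("chr4", 520_000, "C", "T", "TET2_LIKE", "stop_gained"),
    call("chr4", 540_000, "T", "C", "TET2_LIKE", "missense_variant",
         maf=0.004, status="NonSomatic"),  # common polymorphism
    call("chr4", 545_000, "G", "T", "TET2_LIKE", "missense_variant",
         maf=0.004, status="NonSomatic", hotspot=True),  # rescued hotspot
    call("chr1", 120_000, "A", "AT", "NRAS_LIKE", "frameshift",
         hap=(25, 3, 30, 2)),  # low-level indel on BOTH haplotypes
]

merged = merge_callsets(primary, secondary)
reportable = filter_reportable(merged, panel)
final = both_haplotype_indel_filter(reportable, TriageThresholds())

print(f"merged union:          {len(merged)} calls")
print(f"reportable:            {len(reportable)} calls")
print(f"after indel filter:    {len(final)} calls")
for c in final:
    print(f"  {c.contig}:{c.position} {c.ref}>{c.alt}  {c.gene}  "
          f"{c.consequence}  VAF={c.vaf:.2f}  hotspot={c.hotspot}")

# The union holds 6 distinct variants. Reportability removes the intronic
# call and the common (MAF 0.4%) polymorphism but rescues the hotspot at
# the same frequency; the indel filter then removes the artifact seen
# 2-3 times on each haplotype, leaving 3 reportable calls.
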