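"""Phase-informed interpretation: haplotype VAFs, somatic status, cis/trans.

In a tumor of less-than-complete purity, a somatic variant is confined
to one haplotype and that haplotype still carries wild-type reads from
non-tumor cells; a germline heterozygote occupies its haplotype
completely.  This example classifies one of each, then phases a variant
pair into cis/trans.
"""

from myelotriage import (
    GenomicInterval,
    PhaseBlock,
    SmallVariantCall,
    classify_cis_trans,
    classify_somatic_status,
    haplotype_vaf,
)


def call(pos, h1_ref, h1_alt, h2_ref, h2_alt):
    return SmallVariantCall(
        contig="chr1", position=pos, ref="G", alt="A",
        total_depth=h1_ref + h1_alt + h2_ref + h2_alt,
        alt_depth=h1_alt + h2_alt,
        hap1_ref=h1_ref, hap1_alt=h1_alt,
        hap2_ref=h2_ref, hap2_alt=h2_alt,
    )


somatic = call(10_000, h1_ref=12, h1_alt=18, h2_ref=28, h2_alt=0)
germline = call(20_000, h1_ref=0, h1_alt=30, h2_ref=28, h2_alt=0)

for label, c in [("somatic-like", somatic), ("germline-like", germline)]:
    hv = haplotype_vaf(c)
    status = classify_somatic_status(c)
    print(f"{label}: hap1 VAF={hv.hap1_vaf:.2f}  hap2 VAF={hv.hap2_vaf:.2f}  "
          f"mutant=hap{hv.mutant_haplotype}  ->  {status.value}")

blocks = [PhaseBlock(GenomicInterval("chr1", 0, 50_000), "PS1", "S1")]
partner_cis = call(15_000, h1_ref=14, h1_alt=16, h2_ref=30, h2_alt=0)
partner_trans = call(15_000, h1_ref=30, h1_alt=0, h2_ref=13, h2_alt=15)
print("pair on same haplotype:     ",
      classify_cis_trans(somatic, partner_cis, blocks))
print("pair on opposite haplotypes:",
      classify_cis_trans(somatic, partner_trans, blocks))

# The somatic-like call has mutant-haplotype VAF 0.60 with 12 wild-type
# reads on that haplotype -> putative somatic.  The germline-like call
# occupies haplotype 1 completely (VAF 1.00) -> consistent with
# germline.  Both pair classifications require a shared phase block.
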