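"""SV triage: reportable rules, recurrence, insertion-proximity filter.

A short-read caller represents a non-reference mobile-element insertion
as a breakend pair to a distant locus, which looks like a translocation.
This example triages three breakend calls: a genuine recurrent fusion,
an insertion artifact near a known common-insertion site, and a breakend
far from any fusion-partner gene.
"""

from myelotriage import (
    Breakend,
    GenePanel,
    GeneTarget,
    GenomicInterval,
    KnownInsertion,
    RecurrentPair,
    SVCall,
    annotate_recurrent,
    filter_reportable_sv,
    insertion_proximity_filter,
)

panel = GenePanel([
    GeneTarget("FUSA", (GenomicInterval("chr9", 1_000_000, 1_050_000),),
               roles=frozenset({"SV-partner"})),
    GeneTarget("FUSB", (GenomicInterval("chr22", 2_000_000, 2_040_000),),
               roles=frozenset({"SV-partner"})),
])
pairs = [RecurrentPair("FUSA", "FUSB")]
known = [KnownInsertion(GenomicInterval("chr9", 1_020_000, 1_020_001),
                        "population-callset")]


def bnd(name, c1, p1, c2, p2):
    return SVCall(svtype="BND", end1=Breakend(c1, p1, "+"),
                  end2=Breakend(c2, p2, "-"), support=14, abundance=0.38,
                  name=name)


calls = [
    bnd("fusion", "chr9", 1_030_000, "chr22", 2_010_000),
    bnd("insertion_artifact", "chr9", 1_020_400, "chr5", 7_000_000),
    bnd("intergenic", "chr9", 5_000_000, "chr22", 9_000_000),
]

reportable = filter_reportable_sv(calls, panel)
flagged = annotate_recurrent(reportable, pairs, panel)
final = insertion_proximity_filter(flagged, known)

print("input:", [c.name for c in calls])
print("reportable (near a partner gene):", [c.name for c in reportable])
print("final after insertion filter:",
      [f"{c.name} (recurrent={c.recurrent})" for c in final])

# The intergenic breakend fails the 20-kbp partner-gene rule.  The
# artifact breakend sits 400 bp from a known common insertion and is
# removed; the FUSA-FUSB junction is classified recurrent and is exempt
# from that filter by construction.
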