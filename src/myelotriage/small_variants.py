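"""Small-variant (SNV/indel) call-set construction and triage.

Implements the tumor-only reporting rules used in targeted myeloid
profiling: union of a primary (germline-style) and a secondary
(tumor-only) caller, restriction to protein-altering consequences in
panel genes, population-frequency exclusion with hotspot rescue, a
phase-aware both-haplotype indel filter, and the expected-alt-read
coverage-adequacy rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .genomic import GenePanel, GeneTarget, TriageThresholds

#: The twelve consequence terms treated as "nonsynonymous" / reportable.
DEFAULT_CONSEQUENCES = frozenset(
    {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift",
        "stop_lost",
        "start_lost",
        "transcript_ablation",
        "transcript_amplification",
        "inframe_insertion",
        "inframe_deletion",
        "missense_variant",
        "protein_altering_variant",
    }
)


@dataclass(frozen=True)
class ConsequenceWhitelist:
    """Set of consequence annotation terms that qualify for reporting.

    An annotation string may carry several ``&``-separated terms (VEP
    style); the variant qualifies if any term matches.  A term also
    matches when its ``_variant`` suffix is dropped, so the annotation
    ``frameshift_variant`` satisfies the whitelisted term
    ``frameshift``.
    """

    allowed: frozenset[str] = DEFAULT_CONSEQUENCES

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("consequence whitelist must be non-empty")

    def matches(self, consequence: str | None) -> bool:
        if not consequence:
            return False
        for term in consequence.split("&"):
            term = term.strip()
            if term in self.allowed:
                return True
            if term.endswith("_variant") and term[: -len("_variant")] in self.allowed:
                return True
        return False


def normalize_allele(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal allele representation: trim shared suffix then prefix.

    ``position`` is 1-based and advances as leading shared bases are
    trimmed.  (Full left-alignment requires the reference sequence and
    is performed upstream by the callers.)
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


@dataclass(frozen=True)
class SmallVariantCall:
    """One small-variant observation with per-haplotype read support.

    ``position`` is 1-based (VCF convention).  Read support is split
    into haplotype-1, haplotype-2 and unphased compartments whose ref +
    alt counts sum to ``total_depth``.
    """

    contig: str
    position: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    hap1_ref: int = 0
    hap1_alt: int = 0
    hap2_ref: int = 0
    hap2_alt: int = 0
    unphased_ref: int = 0
    unphased_alt: int = 0
    filter_status: str = "PASS"
    callers: tuple[str, ...] = ()
    consequence: str | None = None
    max_population_maf: float | None = None
    hotspot: bool = False
    gene: str | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.contig}:{self.position}")
        if self.alt_depth > self.total_depth:
            raise ValueError("alt_depth exceeds total_depth")
        compartments = (
            self.hap1_ref + self.hap1_alt + self.hap2_ref + self.hap2_alt
            + self.unphased_ref + self.unphased_alt
        )
        if compartments != self.total_depth:
            raise ValueError(
                f"haplotype compartments sum to {compartments}, "
                f"expected total_depth={self.total_depth}"
            )
        alt_sum = self.hap1_alt + self.hap2_alt + self.unphased_alt
        if alt_sum != self.alt_depth:
            raise ValueError(
                f"per-compartment alt reads sum to {alt_sum}, "
                f"expected alt_depth={self.alt_depth}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.total_depth if self.total_depth > 0 else float("nan")

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) == len(self.alt):
            return "MNV"
        return "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized identity: (contig, position, ref, alt)."""
        pos, ref, alt = normalize_allele(self.position, self.ref, self.alt)
        return (self.contig, pos, ref, alt)

    def with_(self, **kwargs) -> "SmallVariantCall":
        return replace(self, **kwargs)


def merge_callsets(
    primary_calls: Sequence[SmallVariantCall],
    secondary_calls: Sequence[SmallVariantCall],
) -> list[SmallVariantCall]:
    """Union of primary PASS calls with secondary PASS/NonSomatic calls.

    Records are keyed by normalized (contig, position, ref, alt).  On a
    key collision the primary caller's support counts are kept and both
    caller labels are preserved for audit.  Output order: primary calls
    in input order, then novel secondary calls in input order.
    """
    merged: dict[tuple, SmallVariantCall] = {}
    for call in primary_calls:
        if call.filter_status != "PASS":
            continue
        if call.key in merged:
            warnings.warn(
                f"duplicate representation of {call.key} in primary callset; "
                "both retained under distinct raw keys" if call != merged[call.key]
                else f"exact duplicate of {call.key} in primary callset",
                stacklevel=2,
            )
            continue
        merged[call.key] = call
    for call in secondary_calls:
        if call.filter_status not in ("PASS", "NonSomatic"):
            continue
        existing = merged.get(call.key)
        if existing is None:
            merged[call.key] = call
        else:
            labels = existing.callers + tuple(
                c for c in call.callers if c not in existing.callers
            )
            merged[call.key] = existing.with_(callers=labels)
    return list(merged.values())


def filter_reportable(
    calls: Sequence[SmallVariantCall],
    panel: GenePanel | Sequence[GeneTarget],
    whitelist: ConsequenceWhitelist | None = None,
    t: TriageThresholds | None = None,
) -> list[SmallVariantCall]:
    """Keep panel-gene, protein-altering, population-rare calls.

    A call is reportable when its gene is on the panel with the
    small-variant role, its consequence is whitelisted, and its maximum
    population minor allele frequency is missing (treated as rare) or
    at most the threshold — unless it is a flagged hotspot, which is
    always rescued from the frequency filter.  Order is preserved.
    """
    whitelist = whitelist or ConsequenceWhitelist()
    t = t or TriageThresholds()
    if not isinstance(panel, GenePanel):
        panel = GenePanel(list(panel))
    sv_genes = {g.symbol for g in panel.with_role("small-variant")}
    kept = []
    for call in calls:
        if call.gene not in sv_genes:
            continue
        if not whitelist.matches(call.consequence):
            continue
        maf = call.max_population_maf
        if maf is not None and maf > t.max_population_maf and not call.hotspot:
            continue
        kept.append(call)
    return kept


def both_haplotype_indel_filter(
    calls: Sequence[SmallVariantCall],
    t: TriageThresholds | None = None,
    germline_rescue_vaf: float = 0.85,
) -> list[SmallVariantCall]:
    """Remove indels observed more than once on both haplotypes.

    Scattered low-level indel errors accumulate alt reads on both
    haplotypes, whereas a true heterozygous somatic indel is confined
    to one.  An indel with >= 2 alt reads on each haplotype is removed
    unless both haplotype-specific VAFs are >= ``germline_rescue_vaf``
    (a genuine germline hom/het-on-both pattern).  SNVs and MNVs pass
    through unchanged.
    """
    kept = []
    for call in calls:
        if call.variant_class != "indel":
            kept.append(call)
            continue
        if call.hap1_alt >= 2 and call.hap2_alt >= 2:
            d1 = call.hap1_ref + call.hap1_alt
            d2 = call.hap2_ref + call.hap2_alt
            v1 = call.hap1_alt / d1
            v2 = call.hap2_alt / d2
            if v1 >= germline_rescue_vaf and v2 >= germline_rescue_vaf:
                kept.append(call)
            continue
        kept.append(call)
    return kept


def expected_alt_reads(reference_vaf: float, coverage: float) -> float:
    """Expected alt-read count for a truth variant at the observed coverage.

    Comparisons against a gold-standard call set restrict recall to
    "assessable" truth variants: those whose expected alt-read count
    (gold-standard VAF x long-read coverage) reaches the configured
    minimum (default >= 3).
    """
    if not 0 <= reference_vaf <= 1:
        raise ValueError(f"reference_vaf must be in [0, 1], got {reference_vaf}")
    if coverage < 0:
        raise ValueError(f"coverage must be >= 0, got {coverage}")
    return reference_vaf * coverage


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation terms (&-separated)">',
    '##INFO=<ID=MAX_AF,Number=1,Type=Float,Description="Maximum population minor allele frequency">',
    '##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Known hotspot mutation">',
    '##INFO=<ID=CALLER,Number=.,Type=String,Description="Caller provenance labels">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref and alt read depths">',
    '##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
    '##FORMAT=<ID=HP1AD,Number=2,Type=Integer,Description="Haplotype 1 ref,alt read depths">',
    '##FORMAT=<ID=HP2AD,Number=2,Type=Integer,Description="Haplotype 2 ref,alt read depths">',
    '##FORMAT=<ID=UNPHAD,Number=2,Type=Integer,Description="Unphased ref,alt read depths">',
    '##FILTER=<ID=NonSomatic,Description="Tumor-only caller germline-like flag">',
    '##FILTER=<ID=LowQual,Description="Low quality">',
]


def write_small_variant_vcf(
    calls: Sequence[SmallVariantCall],
    path: str | Path,
    contigs: dict[str, int] | None = None,
    sample: str = "TUMOR",
) -> None:
    """Write calls to an uncompressed single-sample VCF."""
    if contigs is None:
        contigs = {}
        for c in calls:
            contigs[c.contig] = max(contigs.get(c.contig, 0), c.position + 1000)
    header = pysam.VariantHeader()
    for line in _HEADER_LINES:
        header.add_line(line)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.contig, c.position, c.ref, c.alt)):
            rec = out.new_record(
                contig=call.contig,
                start=call.position - 1,
                alleles=(call.ref, call.alt),
            )
            rec.filter.add(call.filter_status)
            if call.gene:
                rec.info["GENE"] = call.gene
            if call.consequence:
                rec.info["CSQ"] = call.consequence
            if call.max_population_maf is not None:
                rec.info["MAX_AF"] = call.max_population_maf
            if call.hotspot:
                rec.info["HOTSPOT"] = True
            if call.callers:
                rec.info["CALLER"] = call.callers
            s = rec.samples[sample]
            s["DP"] = call.total_depth
            s["AD"] = (call.total_depth - call.alt_depth, call.alt_depth)
            s["VAF"] = call.vaf
            s["HP1AD"] = (call.hap1_ref, call.hap1_alt)
            s["HP2AD"] = (call.hap2_ref, call.hap2_alt)
            s["UNPHAD"] = (call.unphased_ref, call.unphased_alt)
            out.write(rec)


def read_small_variant_vcf(path: str | Path) -> list[SmallVariantCall]:
    """Read a single-sample VCF written in this package's dialect."""
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF, got {samples}")
        sample = samples[0]
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}")
            s = rec.samples[sample]
            hp1 = tuple(s.get("HP1AD") or (0, 0))
            hp2 = tuple(s.get("HP2AD") or (0, 0))
            unph = s.get("UNPHAD")
            dp = s["DP"]
            ad = tuple(s["AD"])
            if unph is None:
                unph = (dp - ad[1] - hp1[0] - hp2[0], ad[1] - hp1[1] - hp2[1])
            filters = list(rec.filter.keys()) or ["PASS"]
            maf = rec.info.get("MAX_AF")
            calls.append(
                SmallVariantCall(
                    contig=rec.chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    total_depth=dp,
                    alt_depth=ad[1],
                    hap1_ref=hp1[0],
                    hap1_alt=hp1[1],
                    hap2_ref=hp2[0],
                    hap2_alt=hp2[1],
                    unphased_ref=unph[0],
                    unphased_alt=unph[1],
                    filter_status=filters[0],
                    callers=tuple(rec.info.get("CALLER", ()) or ()),
                    consequence=rec.info.get("CSQ"),
                    max_population_maf=float(maf) if maf is not None else None,
                    hotspot=bool(rec.info.get("HOTSPOT", False)),
                    gene=rec.info.get("GENE"),
                    sample=sample,
                )
            )
    return calls


def read_hotspots(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read hotspot variant keys from TSV: contig, 1-based position, ref, alt."""
    keys = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            pos, ref, alt = normalize_allele(int(parts[1]), parts[2], parts[3])
            keys.add((parts[0], pos, ref, alt))
    return keys


def apply_hotspots(
    calls: Sequence[SmallVariantCall],
    hotspots: set[tuple[str, int, str, str]],
) -> list[SmallVariantCall]:
    """Set the hotspot flag on calls whose normalized key is listed."""
    return [c.with_(hotspot=True) if c.key in hotspots else c for c in calls]
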