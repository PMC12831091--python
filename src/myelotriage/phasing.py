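"""Phase-informed interpretation of small variants.

Long reads are haplotagged against the sample's own heterozygous
variants, yielding phase blocks and per-haplotype read support for each
call.  This module derives the phase-aware quantities used in tumor-only
interpretation: gene phasing completeness, haplotype-specific VAF,
cis/trans classification of variant pairs, and the putative-somatic
rule — a variant confined to one haplotype whose "mutant" haplotype
still carries wild-type reads cannot be a germline heterozygote in a
tumor of less-than-complete purity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import binomtest

from .genomic import GeneTarget, GenomicInterval, TriageThresholds
from .small_variants import SmallVariantCall


@dataclass(frozen=True)
class PhaseBlock:
    """A contiguous phased interval with a block identity."""

    interval: GenomicInterval
    block_id: str
    sample: str = ""

    @property
    def contig(self) -> str:
        return self.interval.contig


class SomaticStatus(str, enum.Enum):
    PUTATIVE_SOMATIC = "putative-somatic"
    GERMLINE_CONSISTENT = "germline-consistent"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class HaplotypeVAF:
    """Haplotype-specific VAFs and the inferred mutant haplotype.

    A VAF is defined only when the corresponding haplotype has phased
    coverage.  The mutant haplotype is the one carrying the majority of
    phased alt reads; 0 denotes ambiguous (tie, including 0/0).
    """

    hap1_vaf: float | None
    hap2_vaf: float | None
    hap1_depth: int
    hap2_depth: int
    mutant_haplotype: int  # 1 | 2 | 0 (ambiguous)


def validate_phase_blocks(blocks: Sequence[PhaseBlock]) -> None:
    """Check that blocks of one sample on one contig are non-overlapping."""
    by_group: dict[tuple[str, str], list[PhaseBlock]] = {}
    for b in blocks:
        by_group.setdefault((b.sample, b.contig), []).append(b)
    for (sample, contig), group in by_group.items():
        group = sorted(group, key=lambda b: b.interval.start)
        for prev, nxt in zip(group, group[1:]):
            if nxt.interval.start < prev.interval.end:
                raise ValueError(
                    f"overlapping phase blocks on {contig} (sample {sample!r}): "
                    f"{prev.block_id} and {nxt.block_id}"
                )


def gene_phasing_completeness(
    blocks: Sequence[PhaseBlock], gene: GeneTarget
) -> bool:
    """True iff one phase block contains every targeted interval of the gene.

    Complete and continuous phasing across the whole targeted length is
    what permits direct cis/trans assessment of any variant pair in the
    gene.
    """
    if not gene.intervals:
        raise ValueError(f"gene {gene.symbol!r} has no intervals")
    span = gene.span
    for b in blocks:
        if (
            b.contig == span.contig
            and b.interval.start <= span.start
            and b.interval.end >= span.end
        ):
            return True
    return False


def haplotype_vaf(call: SmallVariantCall) -> HaplotypeVAF:
    """Per-haplotype VAFs and mutant-haplotype assignment for one call."""
    d1 = call.hap1_ref + call.hap1_alt
    d2 = call.hap2_ref + call.hap2_alt
    v1 = call.hap1_alt / d1 if d1 > 0 else None
    v2 = call.hap2_alt / d2 if d2 > 0 else None
    if call.hap1_alt > call.hap2_alt:
        mutant = 1
    elif call.hap2_alt > call.hap1_alt:
        mutant = 2
    else:
        mutant = 0
    return HaplotypeVAF(v1, v2, d1, d2, mutant)


def classify_somatic_status(
    call: SmallVariantCall,
    t: TriageThresholds | None = None,
    *,
    method: str = "count",
    min_wildtype_reads: int = 2,
    max_mutant_hap_vaf: float = 0.95,
    binomial_error: float = 0.02,
    alpha: float = 0.05,
) -> SomaticStatus:
    """Classify a call as putative-somatic / germline-consistent.

    Indeterminate when total depth is not strictly above the phased
    coverage floor or the mutant haplotype is ambiguous.  With the
    default ``count`` method, putative-somatic requires >= 2 wild-type
    reads on the mutant haplotype and a mutant-haplotype VAF <= 0.95;
    otherwise germline-consistent.  The ``binomial`` method instead
    rejects a germline haplotype VAF of 1 - ``binomial_error`` with a
    one-sided exact test at level ``alpha``.
    """
    t = t or TriageThresholds()
    if call.total_depth <= t.min_phase_coverage:
        return SomaticStatus.INDETERMINATE
    hv = haplotype_vaf(call)
    if hv.mutant_haplotype == 0:
        return SomaticStatus.INDETERMINATE
    if hv.mutant_haplotype == 1:
        alt, depth, vaf = call.hap1_alt, hv.hap1_depth, hv.hap1_vaf
    else:
        alt, depth, vaf = call.hap2_alt, hv.hap2_depth, hv.hap2_vaf
    wildtype = depth - alt
    if method == "count":
        if wildtype >= min_wildtype_reads and vaf is not None and vaf <= max_mutant_hap_vaf:
            return SomaticStatus.PUTATIVE_SOMATIC
        return SomaticStatus.GERMLINE_CONSISTENT
    if method == "binomial":
        # fewer alt reads than a germline VAF of 1-eps would produce?
        result = binomtest(alt, depth, 1 - binomial_error, alternative="less")
        if result.pvalue < alpha:
            return SomaticStatus.PUTATIVE_SOMATIC
        return SomaticStatus.GERMLINE_CONSISTENT
    raise ValueError(f"unknown method {method!r}")


def _block_containing(
    blocks: Sequence[PhaseBlock], contig: str, position: int
) -> PhaseBlock | None:
    """The phase block covering a 1-based position, if any."""
    for b in blocks:
        if b.contig == contig and b.interval.start <= position - 1 < b.interval.end:
            return b
    return None


def classify_cis_trans(
    a: SmallVariantCall,
    b: SmallVariantCall,
    blocks: Sequence[PhaseBlock],
) -> str:
    """Classify two same-gene calls as ``cis``, ``trans`` or ``unphasable``.

    Both sites must fall inside the same phase block and both must have
    an unambiguous mutant haplotype; then cis means the same haplotype
    carries both variants.
    """
    block_a = _block_containing(blocks, a.contig, a.position)
    block_b = _block_containing(blocks, b.contig, b.position)
    if block_a is None or block_b is None or block_a.block_id != block_b.block_id:
        return "unphasable"
    if block_a.sample != block_b.sample:
        return "unphasable"
    hap_a = haplotype_vaf(a).mutant_haplotype
    hap_b = haplotype_vaf(b).mutant_haplotype
    if hap_a == 0 or hap_b == 0:
        return "unphasable"
    return "cis" if hap_a == hap_b else "trans"


# ---------------------------------------------------------------------------
# Phase block I/O: tab-separated (sample, contig, start, end, block_id)
# ---------------------------------------------------------------------------

def read_phase_blocks(path: str | Path) -> list[PhaseBlock]:
    blocks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            sample, contig, start_s, end_s, block_id = parts[:5]
            try:
                iv = GenomicInterval(contig, int(start_s), int(end_s))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            blocks.append(PhaseBlock(interval=iv, block_id=block_id, sample=sample))
    validate_phase_blocks(blocks)
    return blocks


def write_phase_blocks(blocks: Iterable[PhaseBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tcontig\tstart\tend\tblock_id\n")
        for b in blocks:
            fh.write(
                f"{b.sample}\t{b.contig}\t{b.interval.start}\t{b.interval.end}\t{b.block_id}\n"
            )
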