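"""Structural-variant triage for targeted tumor-only analysis.

Filters caller-level SV records down to the reportable set: PASS
status, minimum read support and abundance, size floors, proximity to
panel genes (DEL/DUP/INS) or fusion-partner genes (BND/INV), subtraction
of population (constitutive) SVs, classification of recurrent driver
rearrangements by fusion-pair proximity, and the insertion-proximity
breakend filter that removes short-read BND artifacts caused by
non-reference mobile-element insertions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from intervaltree import IntervalTree

from .genomic import (
    GenePanel,
    GeneTarget,
    GenomicInterval,
    RecurrentPair,
    TriageThresholds,
    interval_gap,
    point_interval,
)
from .small_variants import ConsequenceWhitelist

LENGTH_BEARING = frozenset({"DEL", "DUP", "INS"})
SV_TYPES = frozenset({"DEL", "DUP", "INS", "INV", "BND"})


@dataclass(frozen=True)
class Breakend:
    """One side of a rearrangement junction (1-based position)."""

    contig: str
    position: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")


@dataclass(frozen=True)
class KnownInsertion:
    """A point-like common-insertion site from a population callset."""

    site: GenomicInterval
    source: str = ""


@dataclass(frozen=True)
class SVCall:
    """One structural variant with breakends, support and annotations."""

    svtype: str
    end1: Breakend
    end2: Breakend | None = None
    svlen: int | None = None
    support: int = 0
    abundance: float = 0.0
    filter_status: str = "PASS"
    genes_hit: tuple[str, ...] = ()
    consequence: str | None = None
    recurrent: bool = False
    sample: str = ""
    platform: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype in ("DEL", "DUP", "INV"):
            if self.end2 is None:
                raise ValueError(f"{self.svtype} requires two breakends")
            if self.end1.contig != self.end2.contig:
                raise ValueError(f"{self.svtype} breakends must share a contig")
            if self.end1.position > self.end2.position:
                raise ValueError(f"{self.svtype} requires end1 <= end2")
        if self.svlen is not None and self.svlen <= 0:
            raise ValueError(f"svlen must be positive, got {self.svlen}")
        if not 0 <= self.abundance <= 1:
            raise ValueError(f"abundance must be in [0, 1], got {self.abundance}")

    @property
    def breakends(self) -> tuple[Breakend, ...]:
        return (self.end1,) if self.end2 is None else (self.end1, self.end2)

    @property
    def length(self) -> int | None:
        if self.svlen is not None:
            return self.svlen
        if self.svtype in ("DEL", "DUP", "INV") and self.end2 is not None:
            return self.end2.position - self.end1.position
        return None

    def with_(self, **kwargs) -> "SVCall":
        return replace(self, **kwargs)


def _gap_to_breakend(bnd: Breakend, gene: GeneTarget) -> float:
    point = point_interval(bnd.contig, bnd.position - 1)
    return min(interval_gap(point, iv) for iv in gene.intervals)


def _near_any_gene(bnd: Breakend, genes: GenePanel, max_gap: int) -> bool:
    return bool(genes.near(bnd.contig, bnd.position - 1, max_gap))


def filter_reportable_sv(
    calls: Sequence[SVCall],
    panel: GenePanel | Sequence[GeneTarget],
    t: TriageThresholds | None = None,
    whitelist: ConsequenceWhitelist | None = None,
) -> list[SVCall]:
    """Apply the reportable-SV rules.

    Universal: PASS filter status, support >= 2 reads, abundance > 5%,
    and record length >= 50 bp for length-bearing types.  Then DEL, DUP
    and INS additionally require length >= 5 kbp, a whitelisted
    consequence, and any breakend within 20 kbp of a panel gene with the
    small-variant or CNV role; BND and INV require either breakend
    within 20 kbp of a fusion-partner gene.
    """
    t = t or TriageThresholds()
    whitelist = whitelist or ConsequenceWhitelist()
    if not isinstance(panel, GenePanel):
        panel = GenePanel(list(panel))
    reported_genes = GenePanel(
        [g for g in panel if g.roles & {"small-variant", "CNV"}]
    )
    partner_genes = GenePanel(panel.with_role("SV-partner"))

    kept = []
    for call in calls:
        if call.svtype in LENGTH_BEARING and call.svlen is None:
            raise ValueError(
                f"{call.svtype} call {call.name or call.end1} lacks svlen"
            )
        if call.filter_status != "PASS":
            continue
        if call.support < t.min_sv_reads:
            continue
        if call.abundance <= t.min_sv_abundance:
            continue
        length = call.length
        if call.svtype in LENGTH_BEARING and length < t.min_sv_record_len:
            continue
        if call.svtype in LENGTH_BEARING:
            if length < t.min_svlen_reportable:
                continue
            if not whitelist.matches(call.consequence):
                continue
            if not any(
                _near_any_gene(b, reported_genes, t.gene_proximity)
                for b in call.breakends
            ):
                continue
        else:  # BND / INV
            if not any(
                _near_any_gene(b, partner_genes, t.gene_proximity)
                for b in call.breakends
            ):
                continue
        kept.append(call)
    return kept


def subtract_population(
    calls: Sequence[SVCall],
    known_svs: Sequence[SVCall],
    match_dist: int = 100,
    min_size_ratio: float = 0.8,
) -> list[SVCall]:
    """Remove calls matching a population (constitutive) SV.

    A call matches a known SV of the same type when every breakend has a
    counterpart within ``match_dist`` bp (either end-pairing) and, for
    length-bearing types, the smaller/larger length ratio is at least
    ``min_size_ratio``.
    """
    by_type: dict[str, list[SVCall]] = {}
    for k in known_svs:
        by_type.setdefault(k.svtype, []).append(k)

    def ends_match(a: Breakend, b: Breakend) -> bool:
        return a.contig == b.contig and abs(a.position - b.position) <= match_dist

    def call_matches(call: SVCall, known: SVCall) -> bool:
        ca, cb = call.end1, call.end2
        ka, kb = known.end1, known.end2
        if (cb is None) != (kb is None):
            return False
        if cb is None:
            geom = ends_match(ca, ka)
        else:
            geom = (ends_match(ca, ka) and ends_match(cb, kb)) or (
                ends_match(ca, kb) and ends_match(cb, ka)
            )
        if not geom:
            return False
        if call.svtype in LENGTH_BEARING:
            la, lb = call.length, known.length
            if la is None or lb is None or max(la, lb) == 0:
                return False
            return min(la, lb) / max(la, lb) >= min_size_ratio
        return True

    kept = []
    for call in calls:
        candidates = by_type.get(call.svtype, [])
        if any(call_matches(call, k) for k in candidates):
            continue
        kept.append(call)
    return kept


def classify_recurrent(
    call: SVCall,
    pairs: Sequence[RecurrentPair],
    panel: GenePanel | Sequence[GeneTarget],
    t: TriageThresholds | None = None,
) -> bool:
    """True iff both breakends fall near the two members of a listed pair.

    "Near" is within the gene-proximity threshold (20 kbp by default);
    either assignment of breakends to pair members qualifies.
    """
    t = t or TriageThresholds()
    if call.end2 is None:
        return False
    if not isinstance(panel, GenePanel):
        panel = GenePanel(list(panel))
    for pair in pairs:
        gene_a = panel.get(pair.gene_a)
        gene_b = panel.get(pair.gene_b)
        if gene_a is None or gene_b is None:
            raise ValueError(
                f"recurrent pair {pair.gene_a}-{pair.gene_b} not resolvable on panel"
            )
        a1 = _gap_to_breakend(call.end1, gene_a) <= t.gene_proximity
        b2 = _gap_to_breakend(call.end2, gene_b) <= t.gene_proximity
        a2 = _gap_to_breakend(call.end2, gene_a) <= t.gene_proximity
        b1 = _gap_to_breakend(call.end1, gene_b) <= t.gene_proximity
        if (a1 and b2) or (a2 and b1):
            return True
    return False


def annotate_recurrent(
    calls: Sequence[SVCall],
    pairs: Sequence[RecurrentPair],
    panel: GenePanel | Sequence[GeneTarget],
    t: TriageThresholds | None = None,
) -> list[SVCall]:
    """Set the ``recurrent`` flag on every call."""
    if not isinstance(panel, GenePanel):
        panel = GenePanel(list(panel))
    return [
        c.with_(recurrent=classify_recurrent(c, pairs, panel, t)) for c in calls
    ]


def insertion_proximity_filter(
    calls: Sequence[SVCall],
    insertions: Sequence[KnownInsertion],
    t: TriageThresholds | None = None,
) -> list[SVCall]:
    """Drop nonrecurrent calls with a breakend near a common insertion.

    Short-read callers represent non-reference mobile-element insertions
    as breakend pairs to distant (often interchromosomal) loci, which
    mimic translocations.  A nonrecurrent call with either end within
    the insertion-proximity distance (2 kbp by default) of a known
    common-insertion site is removed.  Recurrent calls are exempt by
    construction, making their retention structural rather than
    empirical.
    """
    t = t or TriageThresholds()
    trees: dict[str, IntervalTree] = {}
    for ins in insertions:
        tree = trees.setdefault(ins.site.contig, IntervalTree())
        lo = max(0, ins.site.start - t.insertion_proximity)
        hi = ins.site.end + t.insertion_proximity
        tree[lo:hi] = ins

    def near_insertion(bnd: Breakend) -> bool:
        tree = trees.get(bnd.contig)
        return bool(tree is not None and tree.overlap(bnd.position - 1, bnd.position))

    kept = []
    for call in calls:
        if not call.recurrent and any(near_insertion(b) for b in call.breakends):
            continue
        kept.append(call)
    return kept


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_SV_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Structural variant length">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based)">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read count">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant abundance">',
    '##INFO=<ID=GENES,Number=.,Type=String,Description="Gene symbols hit">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence annotation">',
    '##INFO=<ID=RECURRENT,Number=0,Type=Flag,Description="Recurrent fusion-pair rearrangement">',
    '##INFO=<ID=ORIENT2,Number=1,Type=String,Description="Orientation of the second breakend">',
    '##FILTER=<ID=LowQual,Description="Low quality">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
]

_BND_ALT_RE = re.compile(r"^([ACGTN]*)(\[|\])([^:\[\]]+):(\d+)(\[|\])([ACGTN]*)$")


def _bnd_alt(call: SVCall) -> str:
    """VCF bracket notation for a breakend record."""
    mate = call.end2
    assert mate is not None
    if call.end1.orientation == "+":
        if mate.orientation == "-":
            return f"N[{mate.contig}:{mate.position}["
        return f"N]{mate.contig}:{mate.position}]"
    if mate.orientation == "-":
        return f"[{mate.contig}:{mate.position}[N"
    return f"]{mate.contig}:{mate.position}]N"


def _parse_bnd_alt(pos_contig: str, pos: int, alt: str) -> tuple[Breakend, Breakend]:
    m = _BND_ALT_RE.match(alt)
    if m is None:
        raise ValueError(f"unparseable BND ALT {alt!r}")
    leading, open_br, mate_contig, mate_pos, _, trailing = m.groups()
    end1_orient = "+" if leading else "-"
    mate_orient = "-" if open_br == "[" else "+"
    return (
        Breakend(pos_contig, pos, end1_orient),
        Breakend(mate_contig, int(mate_pos), mate_orient),
    )


def write_sv_vcf(
    calls: Sequence[SVCall],
    path: str | Path,
    contigs: dict[str, int] | None = None,
    sample: str = "TUMOR",
) -> None:
    """Write SV calls as an uncompressed VCF (one record per junction)."""
    if contigs is None:
        contigs = {}
        for c in calls:
            for b in c.breakends:
                contigs[b.contig] = max(contigs.get(b.contig, 0), b.position + 1000)
            if c.svtype == "DUP" and c.end2 is not None:
                contigs[c.end1.contig] = max(contigs[c.end1.contig], c.end2.position + 1000)
    header = pysam.VariantHeader()
    for line in _SV_HEADER_LINES:
        header.add_line(line)
    for name, length in sorted(contigs.items()):
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, call in enumerate(
            sorted(calls, key=lambda c: (c.end1.contig, c.end1.position))
        ):
            if call.svtype == "BND":
                alt = _bnd_alt(call)
                stop = call.end1.position
            else:
                alt = f"<{call.svtype}>"
                stop = (
                    call.end2.position if call.end2 is not None else call.end1.position
                )
            rec = out.new_record(
                contig=call.end1.contig,
                start=call.end1.position - 1,
                alleles=("N", alt),
                id=call.name or f"SV{i+1}",
            )
            rec.stop = stop
            rec.filter.add(call.filter_status)
            rec.info["SVTYPE"] = call.svtype
            if call.svlen is not None:
                rec.info["SVLEN"] = call.svlen
            rec.info["SUPPORT"] = call.support
            rec.info["AF"] = call.abundance
            if call.genes_hit:
                rec.info["GENES"] = call.genes_hit
            if call.consequence:
                rec.info["CSQ"] = call.consequence
            if call.recurrent:
                rec.info["RECURRENT"] = True
            if call.svtype != "BND" and call.end2 is not None:
                rec.info["ORIENT2"] = call.end2.orientation
            out.write(rec)


def read_sv_vcf(path: str | Path, sample: str = "", platform: str = "") -> list[SVCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info["SVTYPE"]
            filters = list(rec.filter.keys()) or ["PASS"]
            svlen = rec.info.get("SVLEN")
            if svtype == "BND":
                end1, end2 = _parse_bnd_alt(rec.chrom, rec.pos, rec.alts[0])
            elif svtype == "INS":
                end1 = Breakend(rec.chrom, rec.pos)
                end2 = None
            else:
                orient2 = rec.info.get("ORIENT2", "-")
                end1 = Breakend(rec.chrom, rec.pos, "+")
                end2 = Breakend(rec.chrom, rec.stop, orient2)
            calls.append(
                SVCall(
                    svtype=svtype,
                    end1=end1,
                    end2=end2,
                    svlen=int(svlen) if svlen is not None else None,
                    support=int(rec.info.get("SUPPORT", 0)),
                    abundance=float(rec.info.get("AF", 0.0)),
                    filter_status=filters[0],
                    genes_hit=tuple(rec.info.get("GENES", ()) or ()),
                    consequence=rec.info.get("CSQ"),
                    recurrent=bool(rec.info.get("RECURRENT", False)),
                    sample=sample,
                    platform=platform,
                    name=rec.id or "",
                )
            )
    return calls


def read_known_insertions(path: str | Path) -> list[KnownInsertion]:
    """Read common-insertion sites from BED (contig, start, end[, source])."""
    insertions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            insertions.append(
                KnownInsertion(
                    site=GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                    source=parts[3] if len(parts) > 3 else "",
                )
            )
    return insertions


def write_known_insertions(
    insertions: Iterable[KnownInsertion], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for ins in insertions:
            fh.write(
                f"{ins.site.contig}\t{ins.site.start}\t{ins.site.end}\t{ins.source}\n"
            )
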