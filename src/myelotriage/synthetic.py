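"""Synthetic tumor cohort generator with paired platform emulations.

Generates ground truth with the statistical structure the triage
pipeline assumes — clonal tumor purity, two haplotypes, germline
heterozygous sites at ~1 per kbp, somatic variants confined to one
haplotype at specified bulk VAFs, large CNVs, recurrent translocations
between fusion-pair genes, and non-reference mobile-element insertions —
then emulates a "long-read" call set (per-haplotype binomial read
sampling, phase blocks, read-depth bins, insertions called as INS) and a
"short-read" call set (no phasing; each mobile-element insertion
misrepresented as a breakend pair to a distant repeat-source locus).

Read sampling is count-based: per-site depth is Poisson around the
configured mean (optionally fixed), split binomially between haplotypes,
with a configurable fraction of reads left unphased.  No sequence
content, homopolymer context or GC bias is simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cnv import CNVSegment, DepthBin
from .genomic import (
    GenePanel,
    GeneTarget,
    GenomicInterval,
    RecurrentPair,
    TriageThresholds,
)
from .phasing import PhaseBlock
from .small_variants import SmallVariantCall
from .sv import Breakend, KnownInsertion, SVCall

_BASES = np.array(list("ACGT"))

# RNG substream tags: one independent stream per (stage, sample)
_STAGE_TRUTH, _STAGE_COHORT, _STAGE_LONGREAD, _STAGE_SHORTREAD = 0, 1, 2, 3


@dataclass(frozen=True)
class PlannedCNV:
    """A CNV to plant: half-open interval, state, clonal fraction.

    ``sample`` restricts the event to one sample index; None plants it
    in every sample.
    """

    contig: str
    start: int
    end: int
    state: str  # "loss" | "gain"
    clonal_fraction: float = 1.0
    sample: int | None = None


@dataclass(frozen=True)
class PlannedSV:
    """An SV to plant, either between two panel genes or at coordinates."""

    svtype: str  # "BND" | "DEL" | "DUP" | "INV"
    gene_a: str | None = None
    gene_b: str | None = None
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    sample: int | None = None


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the design being modelled: 26 tumor samples,
    heterozygous sites at 1 per kbp, 2-3 reportable somatic small
    variants per sample, ~52x long-read and ~60x short-read coverage,
    a scaled-down three-contig genome, 12 recurrent translocations
    across the cohort, and ~3 mobile-element insertions per sample
    drawn from a shared pool of common population insertion sites.
    """

    seed: int = 0
    n_samples: int = 26
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 4_000_000, "chr3": 3_000_000}
    )
    purity: float = 0.8
    coverage: dict[str, float] = field(
        default_factory=lambda: {"longread": 52.0, "shortread": 60.0}
    )
    het_density: float = 1e-3
    n_somatic_snvs: int = 2
    n_somatic_indels: int = 1
    somatic_vaf_range: tuple[float, float] = (0.1, 0.4)
    cnv_spec: list[PlannedCNV] | None = None
    sv_spec: list[PlannedSV] | None = None
    n_mobile_insertions: int = 3
    n_shared_insertion_sites: int = 40
    n_population_svs: int = 3
    fp_indel_rate: float = 0.35
    detection_threshold: int = 2
    phased_fraction: float = 0.8
    depth_mode: str = "poisson"  # "poisson" | "fixed"
    read_length: dict[str, float] = field(
        default_factory=lambda: {"longread": 10_000.0, "shortread": 500.0}
    )
    breakend_jitter_sd: dict[str, float] = field(
        default_factory=lambda: {"longread": 15.0, "shortread": 50.0}
    )
    insertion_length_range: tuple[int, int] = (300, 3_000)
    block_length_mean: float = 600_000.0
    block_gap: int = 50_000
    bin_size: int = 100_000
    n_genes: int = 59
    n_pairs: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        lo, hi = self.somatic_vaf_range
        if not 0 < lo <= hi <= self.purity / 2 + 1e-9:
            raise ValueError(
                f"somatic VAF range {self.somatic_vaf_range} must lie in "
                f"(0, purity/2 = {self.purity / 2}]"
            )
        if self.depth_mode not in ("poisson", "fixed"):
            raise ValueError(f"depth_mode must be 'poisson' or 'fixed', got {self.depth_mode!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for cnv in self.cnv_spec or []:
            if cnv.contig not in self.genome:
                raise ValueError(f"CNV contig {cnv.contig!r} not in genome")
            if not 0 <= cnv.start < cnv.end <= self.genome[cnv.contig]:
                raise ValueError(f"CNV [{cnv.start}, {cnv.end}) outside {cnv.contig}")
            if cnv.state not in ("loss", "gain"):
                raise ValueError(f"CNV state must be loss/gain, got {cnv.state!r}")

    def default_cnv_spec(self) -> list[PlannedCNV]:
        """One bin-aligned large loss and gain on the two largest contigs."""
        contigs = sorted(self.genome, key=self.genome.get, reverse=True)
        spec = []
        if contigs:
            length = self.genome[contigs[0]]
            spec.append(PlannedCNV(contigs[0], self.bin_size * 2,
                                   min(length, self.bin_size * 22), "loss"))
        if len(contigs) > 1:
            length = self.genome[contigs[1]]
            spec.append(PlannedCNV(contigs[1], self.bin_size * 4,
                                   min(length, self.bin_size * 20), "gain"))
        return spec


# ---------------------------------------------------------------------------
# Deterministic panel / fusion-pair / repeat-locus layout
# ---------------------------------------------------------------------------

def default_panel(genome: dict[str, int], n_genes: int = 59) -> list[GeneTarget]:
    """Evenly spaced synthetic panel genes, three 2-kbp exons per gene.

    Genes are distributed across contigs proportionally to length and
    named GENE01..GENEnn.  The layout is deterministic given the genome.
    """
    total = sum(genome.values())
    counts: dict[str, int] = {}
    assigned = 0
    contigs = list(genome)
    for i, contig in enumerate(contigs):
        if i == len(contigs) - 1:
            counts[contig] = n_genes - assigned
        else:
            counts[contig] = max(1, round(n_genes * genome[contig] / total))
            assigned += counts[contig]
    genes: list[GeneTarget] = []
    idx = 1
    for contig in contigs:
        n = counts[contig]
        length = genome[contig]
        for j in range(n):
            s = (j + 1) * length // (n + 1)
            exons = (
                GenomicInterval(contig, s, s + 2_000),
                GenomicInterval(contig, s + 11_000, s + 13_000),
                GenomicInterval(contig, s + 22_000, s + 24_000),
            )
            genes.append(GeneTarget(symbol=f"GENE{idx:02d}", intervals=exons))
            idx += 1
    return genes


def default_pairs(panel: Sequence[GeneTarget], n_pairs: int = 8) -> list[RecurrentPair]:
    """Recurrent fusion pairs between genes on different contigs."""
    by_contig: dict[str, list[GeneTarget]] = {}
    for g in panel:
        by_contig.setdefault(g.contig, []).append(g)
    contigs = list(by_contig)
    if len(contigs) < 2:
        raise ValueError("need >= 2 contigs for interchromosomal fusion pairs")
    pairs = []
    for k in range(n_pairs):
        ca = contigs[k % len(contigs)]
        cb = contigs[(k + 1) % len(contigs)]
        ga = by_contig[ca][k % len(by_contig[ca])]
        gb = by_contig[cb][(k // 2) % len(by_contig[cb])]
        if ga.symbol != gb.symbol:
            pairs.append(RecurrentPair(ga.symbol, gb.symbol))
    # dedupe preserving order
    seen: set[frozenset] = set()
    out = []
    for p in pairs:
        key = frozenset((p.gene_a, p.gene_b))
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def mobile_source_loci(
    genome: dict[str, int], panel: Sequence[GeneTarget]
) -> list[tuple[str, int]]:
    """One repeat-family source locus per contig, far from every gene.

    Placed at the center of the widest gap between gene spans (and the
    contig ends), standing in for the fixed genomic homes of mobile
    element families.  No sequence content is modelled.
    """
    loci = []
    for contig, length in genome.items():
        spans = sorted(
            (g.span.start, g.span.end) for g in panel if g.contig == contig
        )
        edges = [0] + [e for _, e in spans]
        starts = [s for s, _ in spans] + [length]
        best = max(range(len(edges)), key=lambda i: starts[i] - edges[i])
        loci.append((contig, (edges[best] + starts[best]) // 2))
    return loci


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSmallVariant:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    vaf: float  # expected bulk VAF
    haplotype: int  # 1 | 2
    is_somatic: bool
    maf: float | None = None
    gene: str | None = None
    consequence: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "indel" if len(self.ref) != len(self.alt) else "MNV"


@dataclass(frozen=True)
class TruthSV:
    name: str
    svtype: str
    end1: Breakend
    end2: Breakend | None
    svlen: int | None
    recurrent: bool
    genes: tuple[str, ...] = ()
    consequence: str | None = None


@dataclass(frozen=True)
class TruthInsertion:
    name: str
    contig: str
    position: int  # 1-based insertion point
    length: int
    source_contig: str
    source_position: int


@dataclass
class SampleTruth:
    sample: str
    purity: float
    germline: list[TruthSmallVariant]
    somatic: list[TruthSmallVariant]
    cnvs: list[PlannedCNV]
    svs: list[TruthSV]
    insertions: list[TruthInsertion]


@dataclass
class TruthTable:
    config: CohortConfig
    panel: list[GeneTarget]
    pairs: list[RecurrentPair]
    samples: list[SampleTruth]
    known_insertions: list[KnownInsertion]
    population_svs: list[SVCall]

    def sample_names(self) -> list[str]:
        return [s.sample for s in self.samples]


def _rng(config: CohortConfig, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage, index])


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return str(_BASES[i]), str(_BASES[j])


def _random_indel_alleles(rng: np.random.Generator) -> tuple[str, str]:
    anchor = str(_BASES[int(rng.integers(4))])
    tail = "".join(_BASES[rng.integers(4, size=int(rng.integers(1, 4)))])
    if rng.random() < 0.5:
        return anchor, anchor + tail  # insertion
    return anchor + tail, anchor  # deletion


def generate_truth(config: CohortConfig) -> TruthTable:
    """Generate the cohort truth table deterministically from the seed."""
    panel_list = default_panel(config.genome, config.n_genes)
    panel = GenePanel(panel_list)
    pairs = default_pairs(panel_list, config.n_pairs)
    sources = mobile_source_loci(config.genome, panel_list)
    cnv_spec = config.cnv_spec if config.cnv_spec is not None else config.default_cnv_spec()
    pair_lookup = {frozenset((p.gene_a, p.gene_b)) for p in pairs}

    sv_spec = config.sv_spec
    if sv_spec is None:
        # 12 recurrent translocations spread across the cohort
        sv_spec = [
            PlannedSV(
                svtype="BND",
                gene_a=pairs[k % len(pairs)].gene_a,
                gene_b=pairs[k % len(pairs)].gene_b,
                sample=k % config.n_samples,
            )
            for k in range(12)
        ]
    for sv in sv_spec:
        if sv.gene_a is not None and panel.get(sv.gene_a) is None:
            raise ValueError(f"planted SV gene {sv.gene_a!r} not on panel")
        if sv.gene_b is not None and panel.get(sv.gene_b) is None:
            raise ValueError(f"planted SV gene {sv.gene_b!r} not on panel")

    cohort_rng = _rng(config, _STAGE_COHORT)

    # shared pool of common (population) insertion sites, inside gene spans
    shared_sites: list[TruthInsertion] = []
    partner_genes = panel.with_role("SV-partner")
    for k in range(config.n_shared_insertion_sites):
        gene = partner_genes[int(cohort_rng.integers(len(partner_genes)))]
        span = gene.span
        pos = int(cohort_rng.integers(span.start + 1, span.end + 1))
        length = int(cohort_rng.integers(*config.insertion_length_range))
        others = [s for s in sources if s[0] != span.contig] or sources
        src = others[int(cohort_rng.integers(len(others)))]
        shared_sites.append(
            TruthInsertion(
                name=f"ins{k:03d}", contig=span.contig, position=pos,
                length=length, source_contig=src[0], source_position=src[1],
            )
        )
    known_insertions = [
        KnownInsertion(
            site=GenomicInterval(s.contig, s.position - 1, s.position),
            source="synthetic-population-callset",
        )
        for s in shared_sites
    ]

    # cohort-level constitutive (population) SVs: germline deletions
    population_svs: list[SVCall] = []
    sv_genes = panel.with_role("small-variant")
    for k in range(config.n_population_svs):
        gene = sv_genes[int(cohort_rng.integers(len(sv_genes)))]
        span = gene.span
        start = int(cohort_rng.integers(span.start + 1, span.start + 5_000))
        svlen = int(cohort_rng.integers(6_000, 15_000))
        population_svs.append(
            SVCall(
                svtype="DEL",
                end1=Breakend(span.contig, start),
                end2=Breakend(span.contig, start + svlen, "-"),
                svlen=svlen,
                support=20,
                abundance=0.5,
                consequence="transcript_ablation",
                genes_hit=(gene.symbol,),
                name=f"popsv{k:02d}",
            )
        )

    samples = []
    for idx in range(config.n_samples):
        rng = _rng(config, _STAGE_TRUTH, idx)
        name = f"S{idx + 1:02d}"
        used: set[tuple[str, int]] = set()

        germline: list[TruthSmallVariant] = []
        for contig, length in config.genome.items():
            n = int(rng.poisson(length * config.het_density))
            positions = np.unique(rng.integers(1, length + 1, size=n))
            haps = rng.integers(1, 3, size=positions.size)
            mafs = rng.uniform(0.005, 0.5, size=positions.size)
            for pos, hap, maf in zip(positions, haps, mafs):
                pos = int(pos)
                if (contig, pos) in used:
                    continue
                used.add((contig, pos))
                ref, alt = _random_snv_alleles(rng)
                hits = panel.near(contig, pos - 1, 0)
                germline.append(
                    TruthSmallVariant(
                        contig=contig, position=pos, ref=ref, alt=alt,
                        vaf=0.5, haplotype=int(hap), is_somatic=False,
                        maf=float(maf),
                        gene=hits[0].symbol if hits else None,
                        consequence="intron_variant",
                    )
                )

        somatic: list[TruthSmallVariant] = []
        small_genes = panel.with_role("small-variant")
        n_som = config.n_somatic_snvs + config.n_somatic_indels
        for k in range(n_som):
            is_indel = k >= config.n_somatic_snvs
            gene = small_genes[int(rng.integers(len(small_genes)))]
            iv = gene.intervals[int(rng.integers(len(gene.intervals)))]
            for _ in range(100):
                pos = int(rng.integers(iv.start + 1, iv.end + 1))
                if (iv.contig, pos) not in used:
                    break
            used.add((iv.contig, pos))
            if is_indel:
                ref, alt = _random_indel_alleles(rng)
                consequence = "frameshift"
            else:
                ref, alt = _random_snv_alleles(rng)
                consequence = "missense_variant"
            vaf = float(rng.uniform(*config.somatic_vaf_range))
            somatic.append(
                TruthSmallVariant(
                    contig=iv.contig, position=pos, ref=ref, alt=alt,
                    vaf=vaf, haplotype=int(rng.integers(1, 3)),
                    is_somatic=True, maf=None,
                    gene=gene.symbol, consequence=consequence,
                )
            )

        cnvs = [c for c in cnv_spec if c.sample is None or c.sample == idx]

        svs: list[TruthSV] = []
        for k, spec in enumerate(sv_spec):
            if spec.sample is not None and spec.sample != idx:
                continue
            if spec.gene_a is not None and spec.gene_b is not None:
                ga, gb = panel.get(spec.gene_a), panel.get(spec.gene_b)
                p1 = int(rng.integers(ga.span.start + 1, ga.span.end + 1))
                p2 = int(rng.integers(gb.span.start + 1, gb.span.end + 1))
                end1 = Breakend(ga.contig, p1, "+" if rng.random() < 0.5 else "-")
                end2 = Breakend(gb.contig, p2, "+" if rng.random() < 0.5 else "-")
                recurrent = frozenset((spec.gene_a, spec.gene_b)) in pair_lookup
                svs.append(
                    TruthSV(
                        name=f"{name}_sv{k:02d}", svtype=spec.svtype,
                        end1=end1, end2=end2, svlen=None,
                        recurrent=recurrent,
                        genes=(spec.gene_a, spec.gene_b),
                    )
                )
            else:
                if spec.contig is None or spec.start is None or spec.end is None:
                    raise ValueError("planted SV needs either two genes or coordinates")
                svlen = spec.end - spec.start
                consequence = {
                    "DEL": "transcript_ablation",
                    "DUP": "transcript_amplification",
                }.get(spec.svtype)
                svs.append(
                    TruthSV(
                        name=f"{name}_sv{k:02d}", svtype=spec.svtype,
                        end1=Breakend(spec.contig, spec.start),
                        end2=Breakend(spec.contig, spec.end, "-"),
                        svlen=svlen if spec.svtype != "INV" else None,
                        recurrent=False,
                        consequence=consequence,
                    )
                )

        chosen = rng.choice(
            len(shared_sites),
            size=min(config.n_mobile_insertions, len(shared_sites)),
            replace=False,
        )
        insertions = [shared_sites[int(i)] for i in sorted(chosen)]

        samples.append(
            SampleTruth(
                sample=name, purity=config.purity,
                germline=germline, somatic=somatic,
                cnvs=cnvs, svs=svs, insertions=insertions,
            )
        )

    return TruthTable(
        config=config, panel=panel_list, pairs=pairs, samples=samples,
        known_insertions=known_insertions, population_svs=population_svs,
    )


# ---------------------------------------------------------------------------
# Platform emulation
# ---------------------------------------------------------------------------

@dataclass
class PlatformCallset:
    """Emulated caller-level outputs for one sample on one platform."""

    platform: str
    sample: str
    primary_small: list[SmallVariantCall]
    secondary_small: list[SmallVariantCall]
    svs: list[SVCall]
    depth_bins: list[DepthBin] = field(default_factory=list)
    phase_blocks: list[PhaseBlock] = field(default_factory=list)
    cnv_segments: list[CNVSegment] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    injected: list[str] = field(default_factory=list)


def _tile_phase_blocks(
    config: CohortConfig, sample: str, rng: np.random.Generator
) -> list[PhaseBlock]:
    blocks = []
    k = 0
    for contig, length in config.genome.items():
        pos = 0
        while pos < length:
            block_len = max(50_000, int(rng.exponential(config.block_length_mean)))
            end = min(pos + block_len, length)
            k += 1
            blocks.append(
                PhaseBlock(
                    interval=GenomicInterval(contig, pos, end),
                    block_id=f"PS{k}",
                    sample=sample,
                )
            )
            pos = end + config.block_gap
    return blocks


def _in_block(blocks: Sequence[PhaseBlock], contig: str, position: int) -> bool:
    for b in blocks:
        if b.contig == contig and b.interval.start <= position - 1 < b.interval.end:
            return True
    return False


def _sample_call(
    v: TruthSmallVariant,
    coverage: float,
    config: CohortConfig,
    rng: np.random.Generator,
    phased: bool,
    sample: str,
) -> SmallVariantCall | None:
    """Draw read counts for one truth variant; None when depth is zero."""
    if config.depth_mode == "fixed":
        depth = int(round(coverage))
    else:
        depth = int(rng.poisson(coverage))
    if depth == 0:
        return None
    n_phased = int(rng.binomial(depth, config.phased_fraction)) if phased else 0
    h1 = int(rng.binomial(n_phased, 0.5))
    h2 = n_phased - h1
    unph = depth - n_phased
    if v.is_somatic:
        hap_rate = min(1.0, 2.0 * v.vaf)  # alt fraction within the mutant haplotype
        bulk_rate = v.vaf
    else:
        hap_rate = 1.0
        bulk_rate = 0.5
    r1 = hap_rate if v.haplotype == 1 else 0.0
    r2 = hap_rate if v.haplotype == 2 else 0.0
    a1 = int(rng.binomial(h1, r1))
    a2 = int(rng.binomial(h2, r2))
    au = int(rng.binomial(unph, bulk_rate))
    alt = a1 + a2 + au
    return SmallVariantCall(
        contig=v.contig, position=v.position, ref=v.ref, alt=v.alt,
        total_depth=depth, alt_depth=alt,
        hap1_ref=h1 - a1, hap1_alt=a1,
        hap2_ref=h2 - a2, hap2_alt=a2,
        unphased_ref=unph - au, unphased_alt=au,
        consequence=v.consequence, max_population_maf=v.maf,
        gene=v.gene, sample=sample,
    )


def _emulate_sv(
    truth_sv: TruthSV,
    coverage: float,
    purity: float,
    jitter_sd: float,
    rng: np.random.Generator,
    sample: str,
    platform: str,
) -> SVCall:
    def jittered(b: Breakend) -> Breakend:
        return Breakend(
            b.contig, max(1, b.position + int(round(rng.normal(0, jitter_sd)))),
            b.orientation,
        )

    e1 = jittered(truth_sv.end1)
    e2 = jittered(truth_sv.end2) if truth_sv.end2 is not None else None
    if e2 is not None and e1.contig == e2.contig and truth_sv.svtype != "BND":
        if e1.position > e2.position:
            e1, e2 = Breakend(e1.contig, e2.position, e1.orientation), Breakend(
                e2.contig, e1.position, e2.orientation
            )
    depth = max(1, int(rng.poisson(coverage)))
    support = int(rng.binomial(depth, purity / 2))
    svlen = truth_sv.svlen
    if svlen is None and truth_sv.svtype in ("DEL", "DUP", "INS"):
        svlen = abs(e2.position - e1.position) if e2 is not None else None
    return SVCall(
        svtype=truth_sv.svtype, end1=e1, end2=e2, svlen=svlen,
        support=support, abundance=support / depth,
        genes_hit=truth_sv.genes, consequence=truth_sv.consequence,
        sample=sample, platform=platform,
        name=f"{platform}_{truth_sv.name}",
    )


def _gene_gap_overlaps(
    panel: GenePanel, blocks: Sequence[PhaseBlock], genome: dict[str, int]
) -> list[GenomicInterval]:
    """Intervals where a panel gene span intersects an unphased gap."""
    out = []
    for gene in panel:
        span = gene.span
        covered = sorted(
            (max(span.start, b.interval.start), min(span.end, b.interval.end))
            for b in blocks
            if b.contig == span.contig and b.interval.start < span.end
            and span.start < b.interval.end
        )
        pos = span.start
        for s, e in covered:
            if s > pos:
                out.append(GenomicInterval(span.contig, pos, s))
            pos = max(pos, e)
        if pos < span.end:
            out.append(GenomicInterval(span.contig, pos, span.end))
    return out


def _effective_cn(cnvs: Sequence[PlannedCNV], purity: float, contig: str,
                  start: int, end: int) -> float:
    """Mean effective copy number of a bin under the planted CNVs."""
    cn = 2.0
    for c in cnvs:
        if c.contig != contig:
            continue
        overlap = max(0, min(end, c.end) - max(start, c.start))
        if overlap == 0:
            continue
        delta = (1.0 if c.state == "gain" else -1.0) * purity * c.clonal_fraction
        cn += delta * overlap / (end - start)
    return cn


def emulate_longread_callset(
    truth: TruthTable, config: CohortConfig | None = None
) -> list[PlatformCallset]:
    """Emulate phased long-read caller outputs for every sample.

    Produces per-haplotype read counts at each truth site (variants
    sampling zero or sub-threshold alt reads are dropped as false
    negatives), phase blocks tiling the genome, binned read depth
    reflecting planted CNVs, SV records with small breakend jitter
    (mobile insertions appear as INS), and false-positive indels
    injected only where panel genes intersect unphased gaps.
    """
    config = config or truth.config
    cov = config.coverage["longread"]
    callsets = []
    for idx, st in enumerate(truth.samples):
        rng = _rng(config, _STAGE_LONGREAD, idx)
        blocks = _tile_phase_blocks(config, st.sample, rng)
        panel = GenePanel(truth.panel)

        primary: list[SmallVariantCall] = []
        secondary: list[SmallVariantCall] = []
        provenance: dict[str, str] = {}
        injected: list[str] = []
        for v in st.germline + st.somatic:
            phased = _in_block(blocks, v.contig, v.position)
            call = _sample_call(v, cov, config, rng, phased, st.sample)
            if call is None or call.alt_depth < config.detection_threshold:
                continue
            call = call.with_(callers=("germline-caller",))
            primary.append(call)
            secondary.append(
                call.with_(
                    callers=("tumor-only-caller",),
                    filter_status="PASS" if v.is_somatic else "NonSomatic",
                )
            )
            provenance[f"{v.contig}:{v.position}:{v.ref}:{v.alt}"] = (
                "somatic" if v.is_somatic else "germline"
            )

        # planted FP indels, only in regions with few phased reads
        n_fp = int(rng.poisson(config.fp_indel_rate))
        gap_regions = _gene_gap_overlaps(panel, blocks, config.genome)
        for _ in range(n_fp if gap_regions else 0):
            region = gap_regions[int(rng.integers(len(gap_regions)))]
            pos = int(rng.integers(region.start + 1, region.end + 1))
            ref, alt = _random_indel_alleles(rng)
            depth = max(5, int(rng.poisson(cov)))
            alt_n = int(rng.integers(2, 5))
            genes = panel.near(region.contig, pos - 1, 0)
            call = SmallVariantCall(
                contig=region.contig, position=pos, ref=ref, alt=alt,
                total_depth=depth, alt_depth=alt_n,
                unphased_ref=depth - alt_n, unphased_alt=alt_n,
                consequence="frameshift",
                gene=genes[0].symbol if genes else None,
                callers=("germline-caller",), sample=st.sample,
            )
            primary.append(call)
            key = f"{call.contig}:{call.position}:{ref}:{alt}"
            provenance[key] = "planted-error"
            injected.append(key)

        svs: list[SVCall] = []
        jitter = config.breakend_jitter_sd["longread"]
        for tsv in st.svs:
            call = _emulate_sv(tsv, cov, st.purity, jitter, rng, st.sample, "longread")
            svs.append(call)
            provenance[call.name] = tsv.name
        for ins in st.insertions:
            pos = max(1, ins.position + int(round(rng.normal(0, jitter))))
            depth = max(1, int(rng.poisson(cov)))
            support = int(rng.binomial(depth, 0.5))
            call = SVCall(
                svtype="INS", end1=Breakend(ins.contig, pos), svlen=ins.length,
                support=support, abundance=support / depth,
                consequence="intron_variant",
                sample=st.sample, platform="longread",
                name=f"longread_{st.sample}_{ins.name}",
            )
            svs.append(call)
            provenance[call.name] = ins.name
        for pop in truth.population_svs:
            call = _emulate_sv(
                TruthSV(
                    name=f"{st.sample}_{pop.name}", svtype=pop.svtype,
                    end1=pop.end1, end2=pop.end2, svlen=pop.svlen,
                    recurrent=False, genes=pop.genes_hit,
                    consequence=pop.consequence,
                ),
                cov, 1.0, jitter, rng, st.sample, "longread",
            )
            svs.append(call)
            provenance[call.name] = pop.name

        bins: list[DepthBin] = []
        rl = config.read_length["longread"]
        for contig, length in config.genome.items():
            for start in range(0, length, config.bin_size):
                end = min(start + config.bin_size, length)
                cn = _effective_cn(st.cnvs, st.purity, contig, start, end)
                expected = cov * cn / 2.0
                n_reads = int(rng.poisson(expected * (end - start) / rl))
                bins.append(
                    DepthBin(
                        GenomicInterval(contig, start, end),
                        n_reads * rl / (end - start),
                    )
                )

        callsets.append(
            PlatformCallset(
                platform="longread", sample=st.sample,
                primary_small=primary, secondary_small=secondary,
                svs=svs, depth_bins=bins, phase_blocks=blocks,
                provenance=provenance, injected=injected,
            )
        )
    return callsets


def emulate_shortread_callset(
    truth: TruthTable, config: CohortConfig | None = None
) -> list[PlatformCallset]:
    """Emulate the short-read (gold standard) caller outputs.

    Short reads cannot be phased against distant heterozygous sites, so
    all read support is unphased.  CNVs are emitted directly as segment
    calls.  Each mobile-element insertion is emitted not as INS but as a
    BND pair whose mate maps to the insertion's repeat-source locus on
    another contig — the failure mode that mimics a translocation.
    """
    config = config or truth.config
    cov = config.coverage["shortread"]
    jitter = config.breakend_jitter_sd["shortread"]
    callsets = []
    for idx, st in enumerate(truth.samples):
        rng = _rng(config, _STAGE_SHORTREAD, idx)
        primary: list[SmallVariantCall] = []
        provenance: dict[str, str] = {}
        for v in st.germline + st.somatic:
            call = _sample_call(v, cov, config, rng, phased=False, sample=st.sample)
            if call is None or call.alt_depth < config.detection_threshold:
                continue
            primary.append(call.with_(callers=("shortread-caller",)))
            provenance[f"{v.contig}:{v.position}:{v.ref}:{v.alt}"] = (
                "somatic" if v.is_somatic else "germline"
            )

        svs: list[SVCall] = []
        for tsv in st.svs:
            call = _emulate_sv(tsv, cov, st.purity, jitter, rng, st.sample, "shortread")
            svs.append(call)
            provenance[call.name] = tsv.name
        for ins in st.insertions:
            pos = max(1, ins.position + int(round(rng.normal(0, jitter))))
            src = max(1, ins.source_position + int(round(rng.normal(0, jitter))))
            depth = max(1, int(rng.poisson(cov)))
            support = int(rng.binomial(depth, 0.5))
            call = SVCall(
                svtype="BND",
                end1=Breakend(ins.contig, pos, "+"),
                end2=Breakend(ins.source_contig, src, "-"),
                support=support, abundance=support / depth,
                sample=st.sample, platform="shortread",
                name=f"shortread_{st.sample}_{ins.name}_bnd",
            )
            svs.append(call)
            provenance[call.name] = ins.name
        for pop in truth.population_svs:
            call = _emulate_sv(
                TruthSV(
                    name=f"{st.sample}_{pop.name}", svtype=pop.svtype,
                    end1=pop.end1, end2=pop.end2, svlen=pop.svlen,
                    recurrent=False, genes=pop.genes_hit,
                    consequence=pop.consequence,
                ),
                cov, 1.0, jitter, rng, st.sample, "shortread",
            )
            svs.append(call)
            provenance[call.name] = pop.name

        segments = [
            CNVSegment(
                interval=GenomicInterval(c.contig, c.start, c.end),
                state=c.state,
                mean_cn=2.0
                + (1.0 if c.state == "gain" else -1.0) * st.purity * c.clonal_fraction,
            )
            for c in st.cnvs
        ]

        callsets.append(
            PlatformCallset(
                platform="shortread", sample=st.sample,
                primary_small=primary, secondary_small=[],
                svs=svs, cnv_segments=segments, provenance=provenance,
            )
        )
    return callsets


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def write_truth_json(truth: TruthTable, path: str | Path) -> None:
    payload = {
        "config": _to_jsonable(truth.config),
        "pairs": [_to_jsonable(p) for p in truth.pairs],
        "samples": [_to_jsonable(s) for s in truth.samples],
        "known_insertions": [_to_jsonable(k) for k in truth.known_insertions],
        "population_svs": [_to_jsonable(p) for p in truth.population_svs],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
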