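"""Coordinate conventions, interval arithmetic, and panel/threshold I/O.

All internal coordinates are 0-based, half-open ``[start, end)``.  VCF
input (1-based) is converted on read and converted back on write.
Contig names are compared as exact strings; no "chr" normalization is
performed unless explicitly enabled by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from intervaltree import IntervalTree

INF = math.inf


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"require end > start >= 0, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneTarget:
    """A panel gene with one or more targeted intervals.

    ``roles`` says which analyses the gene participates in:
    ``small-variant`` (SNV/indel reporting), ``CNV`` (gene-level copy
    number calls) and ``SV-partner`` (fusion-partner proximity for
    breakend/inversion triage).
    """

    symbol: str
    intervals: tuple[GenomicInterval, ...]
    roles: frozenset[str] = frozenset({"small-variant", "CNV", "SV-partner"})

    VALID_ROLES = frozenset({"small-variant", "CNV", "SV-partner"})

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"gene {self.symbol!r} has no intervals")
        contigs = {iv.contig for iv in self.intervals}
        if len(contigs) > 1:
            raise ValueError(
                f"gene {self.symbol!r} spans multiple contigs: {sorted(contigs)}"
            )
        bad = self.roles - self.VALID_ROLES
        if bad:
            raise ValueError(f"unknown roles for {self.symbol!r}: {sorted(bad)}")

    @property
    def contig(self) -> str:
        return self.intervals[0].contig

    @property
    def span(self) -> GenomicInterval:
        """Smallest interval containing every targeted interval."""
        return GenomicInterval(
            self.contig,
            min(iv.start for iv in self.intervals),
            max(iv.end for iv in self.intervals),
        )


@dataclass(frozen=True)
class RecurrentPair:
    """A recurrent fusion gene pair (order-insensitive)."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"recurrent pair members must differ: {self.gene_a!r}")


@dataclass(frozen=True)
class TriageThresholds:
    """Every numeric rule of the triage pipeline in one record.

    Defaults mirror the clinical short-read assay being emulated:
    population-frequency exclusion above 0.1% MAF, SV support of at
    least 2 reads and >5% abundance, size floors of 50 bp (record) and
    5 kbp (reportable DEL/DUP/INS), gene proximity of 20 kbp, CNV
    reporting above 300 kbp with genome-wide comparison classes at
    2/5 Mbp, 1-kbp breakend match distance, 2-kbp insertion proximity,
    >25x phased-coverage floor for somatic classification, >=3 expected
    alt reads for assessability, copy-number cutoffs 1.7 (loss) and 2.3
    (gain) on 100-kbp bins, and 95% confidence intervals.
    """

    max_population_maf: float = 0.001
    min_sv_reads: int = 2
    min_sv_abundance: float = 0.05
    min_svlen_reportable: int = 5_000
    min_sv_record_len: int = 50
    gene_proximity: int = 20_000
    min_cnv_reportable: int = 300_000
    cnv_swgs_min: int = 2_000_000
    cnv_large_min: int = 5_000_000
    sv_match_dist: int = 1_000
    insertion_proximity: int = 2_000
    min_phase_coverage: int = 25
    min_expected_alt: float = 3.0
    cn_loss_cutoff: float = 1.7
    cn_gain_cutoff: float = 2.3
    bin_size: int = 100_000
    confidence: float = 0.95

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if not self.cn_loss_cutoff < 2 < self.cn_gain_cutoff:
            raise ValueError(
                "require cn_loss_cutoff < 2 < cn_gain_cutoff, got "
                f"{self.cn_loss_cutoff}/{self.cn_gain_cutoff}"
            )
        if not 0 < self.confidence < 1:
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TriageThresholds":
        """Load thresholds from a YAML mapping of field names to values.

        Unspecified fields keep their defaults; unknown keys are an error.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown threshold keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)})
        )

    def replace(self, **kwargs) -> "TriageThresholds":
        return replace(self, **kwargs)


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Distance in bp between two half-open intervals.

    Returns 0 when the intervals overlap or abut, the number of bases
    strictly between them otherwise, and ``math.inf`` when they lie on
    different contigs.
    """
    if a.contig != b.contig:
        return INF
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def point_interval(contig: str, position: int) -> GenomicInterval:
    """The 1-bp interval covering a 0-based position."""
    return GenomicInterval(contig, position, position + 1)


class GenePanel:
    """Indexed collection of :class:`GeneTarget` for fast proximity lookup."""

    def __init__(self, genes: Sequence[GeneTarget]):
        symbols = [g.symbol for g in genes]
        dupes = {s for s in symbols if symbols.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate gene symbols in panel: {sorted(dupes)}")
        self.genes = list(genes)
        self._by_symbol = {g.symbol: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.contig, IntervalTree())
            for iv in g.intervals:
                tree[iv.start: iv.end] = g

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def get(self, symbol: str) -> GeneTarget | None:
        return self._by_symbol.get(symbol)

    def with_role(self, role: str) -> list[GeneTarget]:
        return [g for g in self.genes if role in g.roles]

    def near(self, contig: str, position: int, max_gap: float) -> list[GeneTarget]:
        """Genes with any interval within ``max_gap`` bp of a 0-based point.

        The distance is inclusive (``gap <= max_gap``); a point inside a
        gene interval has gap 0.
        """
        tree = self._trees.get(contig)
        if tree is None:
            return []
        if math.isinf(max_gap):
            hits = tree
        else:
            # half-open query window; +1 beyond the pad keeps the
            # boundary gap == max_gap inclusive
            pad = int(max_gap)
            lo = max(0, position - pad)
            hits = tree.overlap(lo, position + pad + 1)
        seen: dict[str, GeneTarget] = {}
        for h in hits:
            seen.setdefault(h.data.symbol, h.data)
        # deterministic panel order
        return [g for g in self.genes if g.symbol in seen]


def within_gene_distance(
    contig: str,
    position: int,
    genes: Sequence[GeneTarget] | GenePanel,
    d: float,
) -> list[GeneTarget]:
    """Every gene with any interval whose gap to the point is <= ``d`` bp.

    ``position`` is 0-based.  ``d`` may be ``math.inf`` to return all
    genes on the point's contig.
    """
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    panel = genes if isinstance(genes, GenePanel) else GenePanel(list(genes))
    return panel.near(contig, position, d)


def read_gene_panel(path: str | Path) -> list[GeneTarget]:
    """Read a gene panel from BED: contig, start, end, gene[, roles].

    Multiple lines with the same gene symbol become one
    :class:`GeneTarget` with several intervals (e.g. targeted exons).
    The optional 5th column is a comma-separated subset of
    ``small-variant,CNV,SV-partner``; absent means all roles.
    Entries are returned in first-appearance file order.
    """
    groups: dict[str, list[GenomicInterval]] = {}
    roles: dict[str, frozenset[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns"
                )
            contig, start_s, end_s, symbol = parts[:4]
            try:
                iv = GenomicInterval(contig, int(start_s), int(end_s))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            role_set = (
                frozenset(p for p in parts[4].split(",") if p)
                if len(parts) >= 5 and parts[4]
                else GeneTarget.VALID_ROLES
            )
            if symbol in groups:
                if roles[symbol] != role_set:
                    raise ValueError(
                        f"{path}:{lineno}: conflicting roles for gene {symbol!r}"
                    )
            else:
                order.append(symbol)
                roles[symbol] = role_set
            groups.setdefault(symbol, []).append(iv)
    return [
        GeneTarget(symbol=s, intervals=tuple(groups[s]), roles=roles[s])
        for s in order
    ]


def read_recurrent_pairs(path: str | Path) -> list[RecurrentPair]:
    """Read recurrent fusion pairs from a two-column tab-separated file."""
    pairs: list[RecurrentPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                pairs.append(RecurrentPair(parts[0], parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return pairs


def write_gene_panel(genes: Iterable[GeneTarget], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for iv in g.intervals:
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{g.symbol}\t"
                    + ",".join(sorted(g.roles))
                    + "\n"
                )


def write_recurrent_pairs(pairs: Iterable[RecurrentPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\n")
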