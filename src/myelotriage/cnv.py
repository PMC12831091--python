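"""Read-depth copy-number segmentation and gene-level CNV calls.

Binned read depth is normalized to copy number against the autosomal
median (diploid baseline), thresholded at hard loss/gain cutoffs
(defaults 1.7 and 2.3), and merged into maximal runs of consecutive
out-of-range bins.  Size filtering, base-pair concordance between two
segment sets, and gene-level affected-gene calls follow the reporting
conventions of the targeted assay: only large alterations are reported
and a gene counts as affected on any >= 1 bp overlap.

No GC or mappability correction is applied: upstream CNV callers
perform these on real data, and the synthetic generator in this package
does not simulate such biases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genomic import GenePanel, GeneTarget, GenomicInterval, TriageThresholds

#: Contig names excluded from the diploid-baseline normalization.
SEX_CONTIGS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class DepthBin:
    """Mean read depth over one fixed-width genomic bin."""

    interval: GenomicInterval
    depth: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth} in {self.interval}")


@dataclass(frozen=True)
class CNVSegment:
    """A maximal run of bins beyond a copy-number cutoff."""

    interval: GenomicInterval
    state: str  # "loss" | "gain"
    mean_cn: float

    def __post_init__(self) -> None:
        if self.state not in ("loss", "gain"):
            raise ValueError(f"state must be 'loss' or 'gain', got {self.state!r}")

    @property
    def length(self) -> int:
        return len(self.interval)


def bins_to_copynumber(
    bins: Sequence[DepthBin],
    sex_contigs: frozenset[str] = SEX_CONTIGS,
) -> list[tuple[DepthBin, float]]:
    """Copy number per bin: 2 x depth / median autosomal depth.

    The median is computed over autosomal bins only, so a diploid
    genome centers at copy number 2 regardless of absolute coverage.
    """
    autosomal = [b.depth for b in bins if b.interval.contig not in sex_contigs]
    if not autosomal:
        raise ValueError("no autosomal bins")
    median = float(np.median(autosomal))
    if median <= 0:
        raise ValueError("median autosomal depth is zero")
    return [(b, 2.0 * b.depth / median) for b in bins]


def segment_copynumber(
    cn_bins: Sequence[tuple[DepthBin, float]],
    t: TriageThresholds | None = None,
    sex_contigs: frozenset[str] = SEX_CONTIGS,
    include_sex: bool = False,
) -> list[CNVSegment]:
    """Merge consecutive out-of-range bins into loss/gain segments.

    Bins are grouped per contig in coordinate order; a run breaks on any
    coordinate gap (no gap bridging) or change of state.  Segment copy
    number is the mean over member bins.  Sex chromosomes are excluded
    unless ``include_sex`` (which applies a ploidy-1 expectation: the
    loss/gain cutoffs are halved).
    """
    t = t or TriageThresholds()

    def state_of(cn: float, haploid: bool) -> str | None:
        loss, gain = (t.cn_loss_cutoff, t.cn_gain_cutoff)
        if haploid:
            loss, gain = loss / 2, gain / 2
        if cn < loss:
            return "loss"
        if cn > gain:
            return "gain"
        return None

    by_contig: dict[str, list[tuple[DepthBin, float]]] = {}
    for b, cn in cn_bins:
        by_contig.setdefault(b.interval.contig, []).append((b, cn))

    segments: list[CNVSegment] = []
    for contig in by_contig:
        haploid = contig in sex_contigs
        if haploid and not include_sex:
            continue
        run: list[tuple[DepthBin, float]] = []
        run_state: str | None = None

        def flush() -> None:
            if run and run_state:
                segments.append(
                    CNVSegment(
                        interval=GenomicInterval(
                            contig, run[0][0].interval.start, run[-1][0].interval.end
                        ),
                        state=run_state,
                        mean_cn=float(np.mean([cn for _, cn in run])),
                    )
                )

        for b, cn in sorted(by_contig[contig], key=lambda x: x[0].interval.start):
            s = state_of(cn, haploid)
            contiguous = bool(run) and run[-1][0].interval.end == b.interval.start
            if s != run_state or (run and not contiguous):
                flush()
                run, run_state = [], s
            if s is not None:
                run.append((b, cn))
        flush()
    return segments


def filter_segments(
    segments: Sequence[CNVSegment], min_length: int
) -> list[CNVSegment]:
    """Keep segments strictly longer than ``min_length`` bp."""
    return [s for s in segments if s.length > min_length]


def _merged_bases(intervals: Sequence[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, spans in by_contig.items():
        spans.sort()
        out: list[tuple[int, int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[contig] = out
    return merged


def basepair_concordance(
    a: Sequence[CNVSegment], b: Sequence[CNVSegment], state: str
) -> float | None:
    """Fraction of bases covered by ``a`` that are also covered by ``b``.

    Both inputs must carry only the given state.  Returns None when
    ``a`` covers no bases (the proportion is undefined).
    """
    for name, segs in (("a", a), ("b", b)):
        bad = {s.state for s in segs} - {state}
        if bad:
            raise ValueError(f"segment set {name} contains states {sorted(bad)}, expected only {state!r}")
    a_merged = _merged_bases([s.interval for s in a])
    b_merged = _merged_bases([s.interval for s in b])
    total = sum(e - s for spans in a_merged.values() for s, e in spans)
    if total == 0:
        return None
    shared = 0
    for contig, a_spans in a_merged.items():
        b_spans = b_merged.get(contig, [])
        i = j = 0
        while i < len(a_spans) and j < len(b_spans):
            s = max(a_spans[i][0], b_spans[j][0])
            e = min(a_spans[i][1], b_spans[j][1])
            if s < e:
                shared += e - s
            if a_spans[i][1] < b_spans[j][1]:
                i += 1
            else:
                j += 1
    return shared / total


def genes_affected(
    segments: Sequence[CNVSegment],
    panel: GenePanel | Sequence[GeneTarget],
) -> dict[str, set[str]]:
    """Panel genes overlapped (>= 1 bp) by loss/gain segments, per state.

    Only genes carrying the CNV role are considered.
    """
    if not isinstance(panel, GenePanel):
        panel = GenePanel(list(panel))
    result: dict[str, set[str]] = {"loss": set(), "gain": set()}
    for gene in panel.with_role("CNV"):
        for seg in segments:
            if any(iv.overlaps(seg.interval) for iv in gene.intervals):
                result[seg.state].add(gene.symbol)
    return result


# ---------------------------------------------------------------------------
# Depth-bin I/O: tab-separated contig, start, end, depth (BED coordinates)
# ---------------------------------------------------------------------------

def read_depth_bins(path: str | Path) -> list[DepthBin]:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["contig", "start", "end", "depth"],
        dtype={"contig": str, "start": int, "end": int, "depth": float},
    )
    return [
        DepthBin(GenomicInterval(r.contig, r.start, r.end), r.depth)
        for r in df.itertuples()
    ]


def write_depth_bins(bins: Iterable[DepthBin], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in bins:
            fh.write(
                f"{b.interval.contig}\t{b.interval.start}\t{b.interval.end}\t{b.depth:.4f}\n"
            )


def write_segments(segments: Iterable[CNVSegment], path: str | Path) -> None:
    """Emit segments as BED with state and mean copy-number columns."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.interval.contig}\t{s.interval.start}\t{s.interval.end}\t"
                f"{s.state}\t{s.mean_cn:.4f}\n"
            )


def read_segments(path: str | Path) -> list[CNVSegment]:
    segments = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            segments.append(
                CNVSegment(
                    interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                    state=parts[3],
                    mean_cn=float(parts[4]),
                )
            )
    return segments
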