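"""End-to-end orchestration of the triage stages.

Each stage is a thin composition of the module-level operations, so a
stage run standalone on intermediate files reproduces the pipeline's
corresponding outputs.  ``run_pipeline`` executes
simulate -> triage-small -> phase-analyze -> cnv -> triage-sv -> evaluate
on a synthetic cohort and writes per-sample reports, a cross-platform
summary and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .cnv import (
    CNVSegment,
    DepthBin,
    bins_to_copynumber,
    filter_segments,
    genes_affected,
    segment_copynumber,
)
from .concordance import (
    MatchResult,
    format_proportion,
    match_small_variants,
    match_svs,
    vaf_correlation,
    wilson_interval,
)
from .genomic import GenePanel, GeneTarget, RecurrentPair, TriageThresholds
from .phasing import (
    PhaseBlock,
    classify_somatic_status,
    gene_phasing_completeness,
    haplotype_vaf,
)
from .small_variants import (
    ConsequenceWhitelist,
    SmallVariantCall,
    apply_hotspots,
    both_haplotype_indel_filter,
    expected_alt_reads,
    filter_reportable,
    merge_callsets,
)
from .sv import (
    KnownInsertion,
    SVCall,
    annotate_recurrent,
    filter_reportable_sv,
    insertion_proximity_filter,
    subtract_population,
)
from .synthetic import (
    CohortConfig,
    PlatformCallset,
    TruthTable,
    emulate_longread_callset,
    emulate_shortread_callset,
    generate_truth,
)


def triage_small(
    primary: Sequence[SmallVariantCall],
    secondary: Sequence[SmallVariantCall],
    panel: GenePanel | Sequence[GeneTarget],
    whitelist: ConsequenceWhitelist | None = None,
    t: TriageThresholds | None = None,
    hotspots: set | None = None,
) -> list[SmallVariantCall]:
    """Caller union, reportability filter, both-haplotype indel filter."""
    merged = merge_callsets(primary, secondary)
    if hotspots:
        merged = apply_hotspots(merged, hotspots)
    reportable = filter_reportable(merged, panel, whitelist, t)
    return both_haplotype_indel_filter(reportable, t)


def analyze_cnv(
    bins: Sequence[DepthBin],
    panel: GenePanel | Sequence[GeneTarget],
    t: TriageThresholds | None = None,
    min_length: int | None = None,
) -> tuple[list[CNVSegment], dict[str, set[str]]]:
    """Normalize, segment, size-filter, and call affected genes."""
    t = t or TriageThresholds()
    cn = bins_to_copynumber(bins)
    segments = segment_copynumber(cn, t)
    segments = filter_segments(
        segments, t.min_cnv_reportable if min_length is None else min_length
    )
    return segments, genes_affected(segments, panel)


def triage_sv(
    calls: Sequence[SVCall],
    panel: GenePanel | Sequence[GeneTarget],
    pairs: Sequence[RecurrentPair],
    population_svs: Sequence[SVCall] = (),
    known_insertions: Sequence[KnownInsertion] = (),
    t: TriageThresholds | None = None,
    whitelist: ConsequenceWhitelist | None = None,
) -> list[SVCall]:
    """Reportable-SV rules, population subtraction, recurrence, MEI filter."""
    if not isinstance(panel, GenePanel):
        panel = GenePanel(list(panel))
    reportable = filter_reportable_sv(calls, panel, t, whitelist)
    reportable = subtract_population(reportable, population_svs)
    reportable = annotate_recurrent(reportable, pairs, panel, t)
    return insertion_proximity_filter(reportable, known_insertions, t)


@dataclass
class SampleReport:
    sample: str
    small_variants: dict[str, list[SmallVariantCall]]  # per platform, reportable
    somatic_status: dict[str, dict[str, str]]  # per platform: key -> status
    phased_genes: dict[str, int]
    cnv_genes: dict[str, dict[str, set[str]]]  # per platform: state -> genes
    svs: dict[str, list[SVCall]]  # per platform, post-triage


@dataclass
class PipelineResult:
    truth: TruthTable
    callsets: dict[str, list[PlatformCallset]]
    reports: list[SampleReport]
    summary: dict


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: CohortConfig,
    outdir: str | Path | None = None,
    t: TriageThresholds | None = None,
) -> PipelineResult:
    """Simulate a cohort and run every triage stage on both platforms.

    The long-read call sets are evaluated against the short-read call
    sets (the gold standard of the emulated design) and against the
    generator's truth table.  When ``outdir`` is given, per-sample
    report tables, the cross-platform summary and a run manifest are
    written there.
    """
    t = t or TriageThresholds()
    started = time.time()
    truth = generate_truth(config)
    panel = GenePanel(truth.panel)
    long_cs = emulate_longread_callset(truth, config)
    short_cs = emulate_shortread_callset(truth, config)

    reports: list[SampleReport] = []
    match_counts = {
        "SNV": {"tp": 0, "fn": 0, "fp": 0},
        "indel": {"tp": 0, "fn": 0, "fp": 0},
    }
    vaf_pairs: list[tuple[float, float]] = []
    recurrent_truth = recurrent_found = recurrent_extra = 0

    for st, lr, sr in zip(truth.samples, long_cs, short_cs):
        small_lr = triage_small(lr.primary_small, lr.secondary_small, panel, t=t)
        small_sr = triage_small(sr.primary_small, [], panel, t=t)

        status_lr = {
            ":".join(map(str, c.key)): classify_somatic_status(c, t).value
            for c in small_lr
        }
        phased = sum(
            gene_phasing_completeness(lr.phase_blocks, g) for g in panel
        )

        segments_lr, genes_lr = analyze_cnv(lr.depth_bins, panel, t)
        genes_sr = genes_affected(
            filter_segments(sr.cnv_segments, t.min_cnv_reportable), panel
        )

        sv_lr = triage_sv(
            lr.svs, panel, truth.pairs, truth.population_svs,
            truth.known_insertions, t,
        )
        sv_sr = triage_sv(
            sr.svs, panel, truth.pairs, truth.population_svs,
            truth.known_insertions, t,
        )

        # long-read vs short-read small variants, with the
        # expected-alt-read assessability mask on the gold standard
        cov_lr = config.coverage["longread"]
        assessable = lambda c: (
            expected_alt_reads(c.vaf, cov_lr) >= t.min_expected_alt
        )
        by_class_sr = {"SNV": [], "indel": []}
        by_class_lr = {"SNV": [], "indel": []}
        for c in small_sr:
            by_class_sr.setdefault(c.variant_class, []).append(c)
        for c in small_lr:
            by_class_lr.setdefault(c.variant_class, []).append(c)
        for vclass in ("SNV", "indel"):
            m = match_small_variants(
                by_class_sr[vclass], by_class_lr[vclass], assessable
            )
            match_counts[vclass]["tp"] += len(m.true_positives)
            match_counts[vclass]["fn"] += len(m.false_negatives)
            match_counts[vclass]["fp"] += len(m.false_positives)
        lr_by_key = {c.key: c for c in small_lr}
        for c in small_sr:
            other = lr_by_key.get(c.key)
            if other is not None:
                vaf_pairs.append((c.vaf, other.vaf))

        truth_recurrent = [s for s in st.svs if s.recurrent]
        found_lr = [c for c in sv_lr if c.recurrent]
        recurrent_truth += len(truth_recurrent)
        truth_names = {s.name for s in truth_recurrent}
        matched = {
            lr.provenance.get(c.name) for c in found_lr
        } & truth_names
        recurrent_found += len(matched)
        recurrent_extra += sum(
            1 for c in found_lr if lr.provenance.get(c.name) not in truth_names
        )

        reports.append(
            SampleReport(
                sample=st.sample,
                small_variants={"longread": small_lr, "shortread": small_sr},
                somatic_status={"longread": status_lr},
                phased_genes={"longread": phased},
                cnv_genes={"longread": genes_lr, "shortread": genes_sr},
                svs={"longread": sv_lr, "shortread": sv_sr},
            )
        )

    summary: dict = {"per_class": {}, "seed": config.seed, "n_samples": config.n_samples}
    for vclass, c in match_counts.items():
        n_truth = c["tp"] + c["fn"]
        n_query = c["tp"] + c["fp"]
        entry = {"n_truth": n_truth, "n_query": n_query, **c}
        if n_truth:
            ci = wilson_interval(c["tp"], n_truth, t.confidence)
            entry["recall"] = ci.point
            entry["recall_ci"] = [ci.lower, ci.upper]
            entry["recall_display"] = format_proportion(c["tp"], n_truth)
        if n_query:
            ci = wilson_interval(c["tp"], n_query, t.confidence)
            entry["precision"] = ci.point
            entry["precision_ci"] = [ci.lower, ci.upper]
        summary["per_class"][vclass] = entry
    summary["vaf_correlation"] = vaf_correlation(vaf_pairs)
    summary["recurrent_sv"] = {
        "truth": recurrent_truth,
        "recalled": recurrent_found,
        "additional": recurrent_extra,
    }
    summary["mean_phased_genes"] = (
        sum(r.phased_genes["longread"] for r in reports) / len(reports)
    )

    result = PipelineResult(
        truth=truth,
        callsets={"longread": long_cs, "shortread": short_cs},
        reports=reports,
        summary=summary,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_reports(result, outdir, t)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": _config_snapshot(config),
            "thresholds": dataclasses.asdict(t),
            "started": started,
            "finished": time.time(),
            "output_digests": {
                p.name: _digest(p)
                for p in sorted(outdir.glob("*"))
                if p.is_file() and p.name != "manifest.json"
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


def _config_snapshot(config: CohortConfig) -> dict:
    from .synthetic import _to_jsonable

    return _to_jsonable(config)


def _write_reports(result: PipelineResult, outdir: Path, t: TriageThresholds) -> None:
    with open(outdir / "small_variants.tsv", "w") as fh:
        fh.write(
            "sample\tplatform\tcontig\tposition\tref\talt\tclass\tvaf\t"
            "hap1_vaf\thap2_vaf\tsomatic_status\n"
        )
        for rep in result.reports:
            for platform, calls in rep.small_variants.items():
                for c in calls:
                    hv = haplotype_vaf(c)
                    status = rep.somatic_status.get(platform, {}).get(
                        ":".join(map(str, c.key)), ""
                    )
                    fh.write(
                        f"{rep.sample}\t{platform}\t{c.contig}\t{c.position}\t"
                        f"{c.ref}\t{c.alt}\t{c.variant_class}\t{c.vaf:.4f}\t"
                        f"{'' if hv.hap1_vaf is None else f'{hv.hap1_vaf:.4f}'}\t"
                        f"{'' if hv.hap2_vaf is None else f'{hv.hap2_vaf:.4f}'}\t"
                        f"{status}\n"
                    )
    with open(outdir / "svs.tsv", "w") as fh:
        fh.write(
            "sample\tplatform\tname\tsvtype\tend1\tend2\tsvlen\tsupport\t"
            "abundance\trecurrent\n"
        )
        for rep in result.reports:
            for platform, calls in rep.svs.items():
                for c in calls:
                    e2 = (
                        f"{c.end2.contig}:{c.end2.position}" if c.end2 else ""
                    )
                    fh.write(
                        f"{rep.sample}\t{platform}\t{c.name}\t{c.svtype}\t"
                        f"{c.end1.contig}:{c.end1.position}\t{e2}\t"
                        f"{c.svlen or ''}\t{c.support}\t{c.abundance:.3f}\t"
                        f"{int(c.recurrent)}\n"
                    )
    with open(outdir / "cnv_genes.tsv", "w") as fh:
        fh.write("sample\tplatform\tstate\tgenes\n")
        for rep in result.reports:
            for platform, states in rep.cnv_genes.items():
                for state, genes in states.items():
                    fh.write(
                        f"{rep.sample}\t{platform}\t{state}\t"
                        + ",".join(sorted(genes))
                        + "\n"
                    )
    summary = dict(result.summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=list))
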