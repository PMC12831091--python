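# Methods

`myelotriage` implements the targeted, tumor-only analysis used in
clinical whole-genome profiling of myeloid cancers (AML/MDS): rather
than interpreting every variant in a genome, the pipeline restricts
caller-level output to the small set of clinically meaningful events —
protein-altering small variants in recurrently mutated genes, large
copy-number alterations, and structural variants near known fusion
genes — and evaluates agreement between sequencing platforms.  All
rules are pure filters over caller-level records; no read-level
processing (basecalling, alignment, variant calling, phasing) is
performed here.

## Coordinates and interval rules

Internal coordinates are 0-based half-open; VCF positions (1-based) are
converted on read and back on write.  Every proximity rule ("within
N kbp") is inclusive (`gap <= N`), and abutting half-open intervals
have gap 0.  Contig names are compared as exact strings; nothing
rewrites `chr` prefixes, so mixed naming surfaces as an input error
rather than a silent mismatch.

## Small-variant triage

The call set is the union of PASS calls from a primary (germline-style)
caller and PASS + `NonSomatic` calls from a secondary tumor-only
caller, keyed by minimal allele representation (shared suffix then
prefix trimmed).  An MNV and its constituent SNVs are deliberately
distinct keys: a partial representation of a multi-nucleotide variant
counts as discordant on both sides of a comparison.  On key collisions
the primary caller's read support is kept and both caller labels are
preserved.

A call is reportable when (i) its gene is on the user-supplied panel
with the small-variant role, (ii) its consequence is on the whitelist of
twelve protein-altering terms (`splice_acceptor_variant`,
`splice_donor_variant`, `stop_gained`, `frameshift`, `stop_lost`,
`start_lost`, `transcript_ablation`, `transcript_amplification`,
`inframe_insertion`, `inframe_deletion`, `missense_variant`,
`protein_altering_variant`; an annotation term also matches with its
`_variant` suffix dropped), and (iii) its maximum population minor
allele frequency is at most 0.1% — with two deliberate choices: a
missing frequency is treated as rare (absence from population databases
is evidence of rarity), and flagged hotspot variants are exempt from
the frequency filter entirely (some bona fide driver hotspots are
polymorphic in population databases).

Small indels are the dominant error mode of long reads.  The
both-haplotype filter removes indels with >= 2 alt reads on *each*
haplotype: a true heterozygous somatic indel is confined to one
haplotype, while scattered noise accrues on both.  Read literally the
rule would also delete genuine germline indels (hom, or het on both
copies), so a call is rescued when both haplotype-specific VAFs are
>= 0.85.  SNVs/MNVs pass through unchanged.

Recall comparisons against a gold-standard call set are restricted to
"assessable" truth variants: those whose expected alt-read count
(gold-standard VAF x mean query coverage) is >= 3.  A variant at 11.8%
VAF under 21x coverage expects 2.5 alt reads and cannot fairly be
scored as a miss.

## Phase-informed interpretation

Long reads are haplotagged upstream; this package consumes per-call
read counts split into haplotype-1 / haplotype-2 / unphased
compartments plus phase-block intervals.

- **Gene phasing completeness**: a gene is completely phased iff a
  single phase block contains every targeted interval — the condition
  for direct cis/trans assessment of any variant pair in the gene.
- **Haplotype-specific VAF**: alt/(alt+ref) per haplotype; the mutant
  haplotype is the argmax of phased alt reads, with ties (including
  0/0) left ambiguous — no arbitrary tiebreak is defensible.
- **Somatic status**: in a tumor of purity < 1, the mutant haplotype of
  a somatic variant still carries wild-type reads from non-tumor cells;
  a germline het occupies its haplotype completely.  The operational
  rule is: indeterminate unless total depth is strictly above 25 reads
  and the mutant haplotype is unambiguous; putative-somatic when the
  mutant haplotype carries >= 2 wild-type reads and its VAF is <= 0.95;
  otherwise germline-consistent.  The numeric cutoffs (2 reads, 0.95)
  are this package's operationalization of the concept; a one-sided
  exact binomial alternative (reject haplotype VAF = 0.98 at alpha =
  0.05) is available via `method="binomial"`.
- **Cis/trans**: defined only when both sites lie in the same phase
  block and both mutant haplotypes are unambiguous; cis means equal
  mutant haplotypes.  The classification is symmetric in its arguments.

Because classification is undefined without phased reads, recovery
experiments score the putative-somatic fraction over *determinate*
calls; sites in phase-block gaps are reported as indeterminate, not as
errors.

## Copy number

Binned mean depth (default 100-kbp bins) is converted to copy number as
`2 x depth / median autosomal depth`; the median is taken over
autosomes only so that a diploid genome centers at CN 2 regardless of
coverage.  Maximal runs of consecutive bins with CN < 1.7 (loss) or
CN > 2.3 (gain) become segments; runs break on any coordinate gap (no
gap bridging — the size filter suppresses fragment noise), and segment
CN is the mean over member bins.  Only segments strictly longer than
300 kbp are reported; 2-Mbp and 5-Mbp thresholds for genome-wide
comparison classes are configurable in the same record.  Sex
chromosomes are excluded by default because the cutoffs presume a
diploid baseline; `include_sex=True` halves the cutoffs (ploidy-1
expectation) instead.  No GC or mappability correction is applied —
upstream CNV callers do this on real data and the synthetic generator
simulates neither bias.

Concordance between two segment sets of one state is the fraction of
base pairs covered by the first that are also covered by the second
(undefined, reported missing, when the first covers nothing).
Gene-level calls list every panel gene with the CNV role overlapping a
segment by >= 1 bp.

## Structural variants

Universal requirements: PASS filter status, >= 2 supporting reads,
abundance strictly > 5%, and >= 50 bp length for length-bearing types.
Then:

- DEL/DUP/INS additionally need length >= 5 kbp, a whitelisted
  consequence, and a breakend within 20 kbp of a reported panel gene;
- BND/INV need either breakend within 20 kbp of a fusion-partner gene
  (ends only; the spanned interval of an inversion is not used).

Population (constitutive) SVs are subtracted: a call is removed when a
known SV of the same type has every breakend within 100 bp (either
end-pairing) and, for length-bearing types, a length ratio >= 0.8.
These two matching parameters are this package's choice (the upstream
tool that inspired them does not document thresholds) and are
configurable.

A call is **recurrent** when its two breakends fall within 20 kbp of
the two members of a listed fusion pair, under either end assignment.

**Insertion-proximity filter.**  Short-read callers represent
non-reference mobile-element insertions as breakend pairs whose mate
maps to the repeat family's genomic source, often on another
chromosome — easily misread as a translocation.  Nonrecurrent calls
with either end within 2 kbp of a known common-insertion site (from a
long-read population callset) are removed.  Recurrent calls are exempt
*by construction*: the observation that the filter never removes known
drivers is made structural rather than left to chance.

## Cross-platform evaluation

Small variants match on exact normalized keys.  SVs match greedily
one-to-one in ascending breakend distance (ties broken by input order):
**strict** requires both ends within 1 kbp (inclusive) under either
end-pairing and equal types; **lenient** requires >= 1 end within 1 kbp
and allows cross-type matches — in particular a short-read BND end may
match a long-read INS site, which is precisely the mobile-element
phenomenon above.  Every strict match is also a lenient match.

Proportions carry Wilson score intervals with the exact normal quantile
(not 1.96); display rounding is half-up at one decimal in percent.  The
Wilson interval is used because validation denominators here are small
(5-60 events) and it behaves at the 0%/100% boundaries where the Wald
interval collapses.  VAF agreement is the Pearson correlation over
variants matched in both platforms (missing with < 2 pairs or zero
variance).

## Synthetic cohort generator

The generator produces ground truth with the statistical structure the
analysis assumes, and emulates the two platforms' caller outputs.  It
is count-based: no sequence content, homopolymer context, chimeras or
GC bias are simulated, so passing tests demonstrate the correctness of
the triage logic under the stated statistical model — not robustness to
real sequencing artifacts.

Defaults are the emulated study's conditions: 26 samples; heterozygous
germline sites as a Poisson process at 1 per kbp with population
frequencies drawn from U(0.005, 0.5); 2 somatic SNVs + 1 somatic indel
per sample in panel exons at bulk VAFs U(0.1, 0.4); tumor purity 0.8;
long-read coverage 52x and short-read 60x; ~0.35 false-positive indels
per sample; 3 mobile-element insertions per sample drawn from a shared
pool of 40 common population insertion sites placed inside gene bodies;
3 cohort-level constitutive deletions present in every sample; and 12
recurrent interchromosomal translocations across the cohort between
listed fusion pairs.  The synthetic genome is three contigs totalling
12 Mb with 59 evenly spaced panel genes (three 2-kbp exons each), eight
interchromosomal fusion pairs, and one repeat-source locus per contig
placed in the widest inter-gene gap (> 20 kbp from every gene).  The
scaled-down genome keeps cohort-scale experiments fast; consequently
the > 5 Mbp genome-wide CNV class exists only as a configurable
threshold at this scale.

Read sampling: per-site depth is Poisson around the configured mean
(`depth_mode="fixed"` gives exact coverage, under which the total
alt-read count at a somatic site is exactly Binomial(coverage, VAF));
a configurable fraction (default 0.8) of reads is phased, split
binomially between haplotypes.  A somatic variant on haplotype *h* at
bulk VAF *v* yields alt reads at rate 2*v* among haplotype-*h* reads
(purity cancels: 2v = purity x clonal fraction) and *v* among unphased
reads; a germline het is fixed on its haplotype.  Variants sampling
fewer than 2 alt reads (configurable) are dropped as false negatives.
Sites falling in the gaps between phase blocks (blocks tile each contig
with exponential lengths, mean 600 kbp, separated by 50-kbp unphased
gaps — reproducing ~90% gene phasing completeness) carry only unphased
reads.  False-positive indels are injected only where panel genes
intersect unphased gaps, mirroring the observation that phase-aware
calling suppresses indel errors elsewhere.

The long-read emulation emits per-haplotype VCF counts, phase blocks,
depth bins (Poisson read counts per bin at the CNV-scaled expected
depth) and SVs with small breakend jitter (sd 15 bp); insertions appear
as INS records of 0.3-3 kbp (below the 5-kbp reportable floor, as in
practice).  The short-read emulation leaves all reads unphased, emits
CNV segments directly (it is the gold-standard assay), jitters
breakends with sd 50 bp, and emits each mobile-element insertion as a
BND pair from the insertion site to the repeat-source locus on another
contig.  Every emulated record carries provenance back to a truth
record or an explicit planted-error label.

All randomness derives from one seed via independent named substreams
per (stage, sample), so stages are individually reproducible and two
runs with the same configuration are byte-identical.

## Numerical and degenerate-input choices

- Wilson bounds are clamped to bracket the point estimate (at k = n the
  analytic upper bound is exactly 1 but floating-point evaluation can
  land 1 ulp below it).
- Zero-depth sites have undefined VAF and are never emitted.
- Undefined proportions (empty denominators) are `None`, never 0 or 1.
- Greedy SV matching breaks distance ties by truth then query input
  order, making reports deterministic.
- `bins_to_copynumber` refuses all-zero autosomal depth rather than
  dividing by zero.

## Known limitations

- No sequence-level realism: error profiles, mappability, GC bias and
  repeat context are out of scope; conclusions about real-data error
  rates cannot be drawn from the synthetic suite.
- The emulated callers are threshold detectors (>= 2 alt reads), not
  statistical callers; genotype likelihoods are not modelled.
- Subclonal CNV deconvolution and allele-specific copy number are not
  implemented; clonal fraction only scales the expected depth shift.
- The insertion filter depends entirely on the supplied
  common-insertion catalog; a private (non-catalogued) insertion will
  still surface as a translocation-like BND pair.
- Breakend orientation is carried through VCF round-trips but not used
  by the matching rules.
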