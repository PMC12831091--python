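"""End-to-end synthetic cohort: simulate, triage, evaluate.

Generates a 4-sample tumor cohort with known ground truth, emulates
long-read and short-read caller outputs, runs every triage stage, and
prints the cross-platform summary: small-variant recall/precision with
Wilson intervals, VAF correlation, gene phasing completeness, and
recurrent-SV recovery.
"""

from myelotriage import CohortConfig
from myelotriage.pipeline import run_pipeline

config = CohortConfig(
    seed=11,
    n_samples=4,
    genome={"chr1": 3_000_000, "chr2": 2_500_000, "chr3": 2_000_000},
)
result = run_pipeline(config)

for vclass, entry in result.summary["per_class"].items():
    lo, hi = entry["recall_ci"]
    print(f"{vclass:6s} recall {entry['recall']:.2f} "
          f"({lo * 100:.1f}%-{hi * 100:.1f}%)  "
          f"precision {entry['precision']:.2f}  "
          f"n_truth={entry['n_truth']}")
print(f"VAF correlation between platforms: "
      f"{result.summary['vaf_correlation']:.3f}")
print(f"mean completely phased genes: "
      f"{result.summary['mean_phased_genes']:.1f} of 59")
rec = result.summary["recurrent_sv"]
print(f"recurrent SVs: {rec['recalled']}/{rec['truth']} recovered, "
      f"{rec['additional']} additional")

# At the default ~52x long-read coverage the planted somatic variants
# are recovered against the short-read gold standard, VAFs correlate
# strongly, most panel genes fall inside a single phase block, and all
# planted recurrent translocations survive triage with no false
# recurrent calls.
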