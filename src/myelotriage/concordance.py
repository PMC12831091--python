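"""Cross-platform concordance: matching, recall/precision, Wilson CIs.

Small variants are matched on exact normalized keys; structural
variants by breakend distance under a strict (both ends within 1 kbp)
or lenient (at least one end within 1 kbp) definition with greedy
one-to-one assignment.  Proportions carry Wilson score intervals and
are displayed with half-up rounding at one decimal in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Hashable, Sequence

from scipy.stats import norm, pearsonr

from .small_variants import SmallVariantCall
from .sv import Breakend, SVCall


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with a Wilson score confidence interval."""

    numerator: int
    denominator: int
    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"require 0 <= numerator <= denominator, got "
                f"{self.numerator}/{self.denominator}"
            )
        if not (0 <= self.lower <= self.point <= self.upper <= 1):
            raise ValueError(
                f"require 0 <= lower <= point <= upper <= 1, got "
                f"{self.lower}/{self.point}/{self.upper}"
            )


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    Uses the exact normal quantile z at (1 + confidence) / 2.  Unlike
    the Wald interval, the Wilson interval is well behaved at the
    boundaries (0 or all successes) and at small n, which is why it is
    the convention for recall/precision error bars on small validation
    sets.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not 0 <= successes <= trials:
        raise ValueError(f"require 0 <= successes <= trials, got {successes}/{trials}")
    z = norm.ppf((1 + confidence) / 2)
    p = successes / trials
    denom = 1 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = z * math.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials)) / denom
    return ProportionCI(
        numerator=successes,
        denominator=trials,
        point=p,
        lower=min(p, max(0.0, center - half)),
        upper=max(p, min(1.0, center + half)),
    )


def format_proportion(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Percentage display with half-up rounding, e.g. (110, 156, 1) -> '70.5%'."""
    if denominator < 1:
        raise ValueError(f"denominator must be >= 1, got {denominator}")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(quantum, rounding=ROUND_HALF_UP)}%"


@dataclass
class MatchResult:
    """Outcome of matching a query call set against a truth set.

    The three key lists are disjoint; TP + FN spans the truth set and
    TP + FP spans the query set.  ``match_mode`` records, per matched
    truth key, whether the match was strict or lenient.
    """

    true_positives: list[Hashable]
    false_negatives: list[Hashable]
    false_positives: list[Hashable]
    match_mode: dict[Hashable, str] = field(default_factory=dict)
    pairs: list[tuple[Hashable, Hashable]] = field(default_factory=list)

    @property
    def recall(self) -> float | None:
        n = len(self.true_positives) + len(self.false_negatives)
        return len(self.true_positives) / n if n else None

    @property
    def precision(self) -> float | None:
        n = len(self.true_positives) + len(self.false_positives)
        return len(self.true_positives) / n if n else None

    def recall_ci(self, confidence: float = 0.95) -> ProportionCI:
        return wilson_interval(
            len(self.true_positives),
            len(self.true_positives) + len(self.false_negatives),
            confidence,
        )

    def precision_ci(self, confidence: float = 0.95) -> ProportionCI:
        return wilson_interval(
            len(self.true_positives),
            len(self.true_positives) + len(self.false_positives),
            confidence,
        )


def match_small_variants(
    truth: Sequence[SmallVariantCall],
    query: Sequence[SmallVariantCall],
    assessable: Callable[[SmallVariantCall], bool] | None = None,
) -> MatchResult:
    """Match small variants by exact normalized key.

    An MNV and its constituent SNVs have distinct keys, so a partial
    representation counts as both a false negative and a false positive.
    ``assessable`` optionally masks truth records (e.g. the expected
    alt-read coverage-adequacy rule) before recall computation; masked
    truth keys are also excluded from the false-positive side.
    """
    masked: set = set()
    if assessable is not None:
        masked = {c.key for c in truth if not assessable(c)}
    truth_keys = [c.key for c in truth if c.key not in masked]
    query_keys = [c.key for c in query if c.key not in masked]
    truth_set, query_set = set(truth_keys), set(query_keys)
    tp = [k for k in truth_keys if k in query_set]
    fn = [k for k in truth_keys if k not in query_set]
    fp = [k for k in query_keys if k not in truth_set]
    return MatchResult(tp, fn, fp, match_mode={k: "strict" for k in tp})


def _sv_key(call: SVCall, index: int) -> Hashable:
    return (call.name or f"#{index}", call.svtype, call.end1.contig, call.end1.position)


def _end_distance(a: Breakend, b: Breakend) -> float:
    if a.contig != b.contig:
        return math.inf
    return abs(a.position - b.position)


def _pair_distances(t: SVCall, q: SVCall) -> tuple[float, float]:
    """(strict_distance, lenient_distance) between two calls.

    Strict distance pairs both ends (best of the two assignments,
    summing end distances); lenient distance is the single closest
    end-to-end distance.
    """
    te, qe = t.breakends, q.breakends
    lenient = min(_end_distance(a, b) for a in te for b in qe)
    if len(te) == 2 and len(qe) == 2:
        direct = max(_end_distance(te[0], qe[0]), _end_distance(te[1], qe[1]))
        swapped = max(_end_distance(te[0], qe[1]), _end_distance(te[1], qe[0]))
        strict = min(direct, swapped)
    elif len(te) == 1 and len(qe) == 1:
        strict = lenient
    else:
        strict = math.inf
    return strict, lenient


def _types_compatible_strict(a: str, b: str) -> bool:
    return a == b


def _types_compatible_lenient(a: str, b: str) -> bool:
    # a BND end may match an INS site: short reads represent unresolved
    # insertions as distant breakend pairs
    return True


def match_svs(
    truth: Sequence[SVCall],
    query: Sequence[SVCall],
    t=None,
    mode: str = "strict",
) -> MatchResult:
    """Greedy one-to-one SV matching by breakend distance.

    ``strict`` requires both ends of a call to coincide with the
    counterpart's ends within the match distance (1 kbp by default,
    inclusive) under either end-pairing, and compatible (equal) types.
    ``lenient`` requires at least one end within the match distance and
    allows cross-type matches.  Candidate pairs are assigned greedily in
    ascending distance, ties broken by truth then query input order.
    """
    from .genomic import TriageThresholds

    t = t or TriageThresholds()
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    max_dist = t.sv_match_dist

    candidates: list[tuple[float, int, int, str]] = []
    for i, tc in enumerate(truth):
        for j, qc in enumerate(query):
            strict_d, lenient_d = _pair_distances(tc, qc)
            if (
                strict_d <= max_dist
                and _types_compatible_strict(tc.svtype, qc.svtype)
            ):
                candidates.append((strict_d, i, j, "strict"))
            elif (
                mode == "lenient"
                and lenient_d <= max_dist
                and _types_compatible_lenient(tc.svtype, qc.svtype)
            ):
                candidates.append((lenient_d, i, j, "lenient"))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    matched_truth: dict[int, str] = {}
    matched_query: set[int] = set()
    pairs: list[tuple[Hashable, Hashable]] = []
    for dist, i, j, kind in candidates:
        if i in matched_truth or j in matched_query:
            continue
        matched_truth[i] = kind
        matched_query.add(j)
        pairs.append((_sv_key(truth[i], i), _sv_key(query[j], j)))

    tp = [_sv_key(c, i) for i, c in enumerate(truth) if i in matched_truth]
    fn = [_sv_key(c, i) for i, c in enumerate(truth) if i not in matched_truth]
    fp = [_sv_key(c, j) for j, c in enumerate(query) if j not in matched_query]
    mode_map = {
        _sv_key(truth[i], i): kind for i, kind in matched_truth.items()
    }
    return MatchResult(tp, fn, fp, match_mode=mode_map, pairs=pairs)


def vaf_correlation(paired_vafs: Sequence[tuple[float, float]]) -> float | None:
    """Pearson correlation of VAFs for variants matched in both platforms.

    Returns None (reported as missing) with fewer than two pairs or when
    either side has zero variance.
    """
    if len(paired_vafs) < 2:
        return None
    x = [p[0] for p in paired_vafs]
    y = [p[1] for p in paired_vafs]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return None
    r, _ = pearsonr(x, y)
    return float(r)
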