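import numpy as np
import pytest
from scipy.stats import norm

from myelotriage.concordance import (
    format_proportion,
    match_small_variants,
    match_svs,
    vaf_correlation,
    wilson_interval,
)
from myelotriage.genomic import TriageThresholds
from myelotriage.small_variants import SmallVariantCall
from myelotriage.sv import Breakend, SVCall


def call(pos, ref="A", alt="T", vaf_depth=(10, 30)):
    alt_d, total = vaf_depth
    return SmallVariantCall(
        contig="chr1", position=pos, ref=ref, alt=alt,
        total_depth=total, alt_depth=alt_d,
        unphased_ref=total - alt_d, unphased_alt=alt_d,
    )


def sv(p1, p2, svtype="BND", c1="chr1", c2="chr2", name=""):
    return SVCall(
        svtype=svtype, end1=Breakend(c1, p1, "+"), end2=Breakend(c2, p2, "-"),
        support=10, abundance=0.3, name=name,
        svlen=abs(p2 - p1) if svtype in ("DEL", "DUP", "INS") else None,
    )


class TestWilsonInterval:
    @pytest.mark.parametrize(
        "k, n, lower, upper",
        [
            (3, 7, 0.158, 0.750),
            (19, 19, 0.832, 1.000),
            (0, 10, 0.000, 0.278),
        ],
    )
    def test_known_intervals(self, k, n, lower, upper):
        ci = wilson_interval(k, n, 0.95)
        assert ci.lower == pytest.approx(lower, abs=5e-4)
        assert ci.upper == pytest.approx(upper, abs=5e-4)
        assert ci.point == pytest.approx(k / n)

    def test_agrees_with_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        rng = np.random.default_rng(31)
        for _ in range(200):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, hi = statsmodels.proportion_confint(k, n, alpha=0.05,
                                                    method="wilson")
            ci = wilson_interval(k, n, 0.95)
            assert ci.lower == pytest.approx(lo, abs=1e-9)
            assert ci.upper == pytest.approx(hi, abs=1e-9)

    def test_converges_to_normal_approximation(self):
        n, p = 10**6, 0.5
        k = int(n * p)
        ci = wilson_interval(k, n, 0.95)
        z = norm.ppf(0.975)
        half = z * np.sqrt(p * (1 - p) / n)
        assert ci.lower == pytest.approx(p - half, abs=1e-4)
        assert ci.upper == pytest.approx(p + half, abs=1e-4)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestFormatProportion:
    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [
            (110, 156, 1, "70.5%"),
            (78, 167, 1, "46.7%"),
            (63, 109, 0, "58%"),
            (1, 8, 1, "12.5%"),
            (1, 16, 1, "6.3%"),  # half-up: 6.25 -> 6.3
        ],
    )
    def test_rounding(self, num, den, decimals, expected):
        assert format_proportion(num, den, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            format_proportion(1, 0)


class TestMatchSmallVariants:
    def test_identical_sets(self):
        calls = [call(100), call(200)]
        m = match_small_variants(calls, list(calls))
        assert m.recall == 1.0 and m.precision == 1.0

    def test_partial_mnv_is_both_fn_and_fp(self):
        truth = [call(100, ref="AC", alt="TG")]
        query = [call(100, ref="A", alt="T")]
        m = match_small_variants(truth, query)
        assert len(m.false_negatives) == 1
        assert len(m.false_positives) == 1
        assert m.true_positives == []

    def test_assessability_mask_excludes_truth(self):
        low = call(100, vaf_depth=(2, 30))
        high = call(200, vaf_depth=(15, 30))
        m = match_small_variants([low, high], [call(200, vaf_depth=(14, 28))],
                                 assessable=lambda c: c.vaf >= 0.2)
        assert m.recall == 1.0
        assert len(m.false_negatives) == 0

    def test_matches_brute_force_set_comparison(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            truth_pos = set(map(int, rng.choice(1000, rng.integers(0, 40), replace=False)))
            query_pos = set(map(int, rng.choice(1000, rng.integers(0, 40), replace=False)))
            m = match_small_variants(
                [call(p + 1) for p in sorted(truth_pos)],
                [call(p + 1) for p in sorted(query_pos)],
            )
            assert len(m.true_positives) == len(truth_pos & query_pos)
            assert len(m.false_negatives) == len(truth_pos - query_pos)
            assert len(m.false_positives) == len(query_pos - truth_pos)


class TestMatchSVs:
    def test_both_ends_close_is_strict(self, thresholds):
        truth = [sv(10_000, 50_000)]
        query = [sv(10_800, 50_800)]
        m = match_svs(truth, query, thresholds, "strict")
        assert m.recall == 1.0
        assert list(m.match_mode.values()) == ["strict"]

    def test_one_end_close_is_lenient_only(self, thresholds):
        truth = [sv(10_000, 50_000)]
        query = [sv(10_500, 55_000)]
        assert match_svs(truth, query, thresholds, "strict").recall == 0.0
        m = match_svs(truth, query, thresholds, "lenient")
        assert m.recall == 1.0
        assert list(m.match_mode.values()) == ["lenient"]

    def test_both_ends_far_never_match(self, thresholds):
        truth = [sv(10_000, 50_000)]
        query = [sv(11_500, 51_500)]
        assert match_svs(truth, query, thresholds, "lenient").recall == 0.0

    def test_swapped_end_pairing_is_strict(self, thresholds):
        truth = [sv(10_000, 50_000, c1="chr1", c2="chr1")]
        query = [SVCall(svtype="BND", end1=Breakend("chr1", 49_900, "+"),
                        end2=Breakend("chr1", 10_100, "-"),
                        support=5, abundance=0.3)]
        m = match_svs(truth, query, thresholds, "strict")
        assert m.recall == 1.0

    def test_bnd_end_matches_ins_site_leniently(self, thresholds):
        # short-read BND at a mobile-element insertion point
        ins = SVCall(svtype="INS", end1=Breakend("chr1", 20_000), svlen=1_600,
                     support=10, abundance=0.5)
        bnd = sv(20_300, 9_000_000, c1="chr1", c2="chr9")
        assert match_svs([ins], [bnd], thresholds, "strict").recall == 0.0
        assert match_svs([ins], [bnd], thresholds, "lenient").recall == 1.0

    def test_strict_matches_subset_of_lenient_and_one_to_one(self, thresholds):
        rng = np.random.default_rng(23)
        for _ in range(60):
            def random_calls(n):
                return [
                    sv(int(rng.integers(1, 200_000)), int(rng.integers(1, 200_000)),
                       name=f"c{i}")
                    for i in range(n)
                ]
            truth = random_calls(int(rng.integers(0, 12)))
            query = random_calls(int(rng.integers(0, 12)))
            strict = match_svs(truth, query, thresholds, "strict")
            lenient = match_svs(truth, query, thresholds, "lenient")
            assert len(strict.true_positives) <= len(lenient.true_positives)
            # strict matches remain matched under lenient mode
            assert set(strict.true_positives) <= set(lenient.true_positives)
            for m in (strict, lenient):
                truth_side = [p[0] for p in m.pairs]
                query_side = [p[1] for p in m.pairs]
                assert len(truth_side) == len(set(truth_side))
                assert len(query_side) == len(set(query_side))
                assert set(m.true_positives) | set(m.false_negatives) == {
                    (c.name or f"#{i}", c.svtype, c.end1.contig, c.end1.position)
                    for i, c in enumerate(truth)
                }

    def test_recomputed_rates_equal_reported(self, thresholds):
        truth = [sv(10_000, 50_000), sv(80_000, 120_000)]
        query = [sv(10_100, 50_100), sv(300_000, 400_000)]
        m = match_svs(truth, query, thresholds, "strict")
        tp, fn, fp = map(len, (m.true_positives, m.false_negatives, m.false_positives))
        assert m.recall == tp / (tp + fn)
        assert m.precision == tp / (tp + fp)


class TestVafCorrelation:
    def test_identity_line(self):
        pairs = [(x, x) for x in (0.1, 0.2, 0.5, 0.8)]
        assert vaf_correlation(pairs) == pytest.approx(1.0)

    def test_anti_ordered(self):
        pairs = [(x, 1 - x) for x in (0.1, 0.2, 0.5, 0.8)]
        assert vaf_correlation(pairs) == pytest.approx(-1.0)

    def test_degenerate_returns_missing(self):
        assert vaf_correlation([(0.5, 0.5)]) is None
        assert vaf_correlation([(0.5, 0.1), (0.5, 0.9)]) is None

    def test_matches_analytic_correlation_of_generating_model(self):
        # x = s + e1, y = s + e2 with shared/noise variances known:
        # rho = var_s / (var_s + var_e)
        rng = np.random.default_rng(12)
        var_s, var_e = 0.02, 0.005
        n = 4000
        s = rng.normal(0.4, np.sqrt(var_s), n)
        x = s + rng.normal(0, np.sqrt(var_e), n)
        y = s + rng.normal(0, np.sqrt(var_e), n)
        expected = var_s / (var_s + var_e)
        assert vaf_correlation(list(zip(x, y))) == pytest.approx(expected, abs=0.03)


try:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(1, 2_000).flatmap(
        lambda n: st.tuples(st.integers(0, n), st.just(n))
    ), st.floats(0.5, 0.999))
    @settings(derandomize=True, max_examples=300)
    def test_wilson_interval_is_ordered_and_bounded(kn, confidence):
        k, n = kn
        ci = wilson_interval(k, n, confidence)
        assert 0 <= ci.lower <= ci.point <= ci.upper <= 1
        assert ci.point == k / n

    @given(st.integers(1, 500).flatmap(
        lambda n: st.tuples(st.integers(0, n), st.just(n))
    ))
    @settings(derandomize=True, max_examples=200)
    def test_wider_confidence_widens_interval(kn):
        k, n = kn
        narrow = wilson_interval(k, n, 0.90)
        wide = wilson_interval(k, n, 0.99)
        assert wide.lower <= narrow.lower
        assert wide.upper >= narrow.upper

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
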