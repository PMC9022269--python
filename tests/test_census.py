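"""End-anchoring filters, bin calls, census aggregation and regression."""

import math

import numpy as np
import pytest

from l1utr.align import AlignmentHit
from l1utr.census import (
    CensusError,
    FilterConfig,
    StartCall,
    age_regression,
    bin_labels,
    call_start,
    census,
    correlation_pvalue,
    dedup_patterns,
    filter_hit,
    pairwise_identity,
    percent,
    pooled_census,
)
from l1utr.promoter_model import PromoterModel, build_extended_query


@pytest.fixture(scope="module")
def query212():
    """All-212-bp-monomer query with a 205-bp tether (length 2537)."""
    model = PromoterModel("S", ("A" * 212,), "T" * 205, pattern_id="II")
    return build_extended_query(model, 11)


def _hit(query, qstart, qend, sstart=1, minus=False, locus="locus1"):
    return AlignmentHit(
        qseqid="q",
        sseqid=locus,
        pident=99.0,
        length=qend - qstart + 1,
        mismatch=0,
        gapopen=0,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=sstart + (qend - qstart),
        score=float(qend - qstart + 1),
        minus_strand=minus,
    )


class TestFilter:
    def test_ideal_full_length_locus_passes(self, query212):
        hit = _hit(query212, 1, len(query212), sstart=1)
        assert filter_hit(hit, query212).passed

    def test_tether_tail_window_boundaries(self, query212):
        lq = len(query212)
        # last 10 bases are positions lq-9..lq
        assert filter_hit(_hit(query212, 1, lq - 9), query212).passed
        verdict = filter_hit(_hit(query212, 1, lq - 10), query212)
        assert not verdict.passed and verdict.reason == "tether-3'-truncated"

    def test_subject_head_window_boundaries(self, query212):
        lq = len(query212)
        assert filter_hit(_hit(query212, 1, lq, sstart=10), query212).passed
        verdict = filter_hit(_hit(query212, 1, lq, sstart=11), query212)
        assert not verdict.passed and verdict.reason == "not-5'-anchored"

    def test_minus_orientation_rejected(self, query212):
        verdict = filter_hit(
            _hit(query212, 1, len(query212), minus=True), query212
        )
        assert not verdict.passed and verdict.reason == "minus-orientation"

    def test_shrinking_windows_never_admit(self, query212):
        """Monotonicity: any hit passing narrow windows passes wider ones."""
        rng = np.random.default_rng(12)
        lq = len(query212)
        for _ in range(200):
            qend = int(rng.integers(lq - 25, lq + 1))
            sstart = int(rng.integers(1, 26))
            hit = _hit(query212, 100, qend, sstart=sstart)
            for wt, ws in ((5, 5), (8, 3), (10, 10)):
                narrow = filter_hit(hit, query212, FilterConfig(wt, ws))
                wide = filter_hit(
                    hit, query212, FilterConfig(wt + 5, ws + 5)
                )
                if narrow.passed:
                    assert wide.passed


class TestCallStart:
    def test_full_third_monomer(self, query212):
        hit = _hit(query212, query212.position_of("M3", 1), len(query212))
        call = call_start(hit, query212)
        assert call.bin == "M3" and call.offset == 1
        assert call.monomer_count == pytest.approx(3.0)
        assert call.averaged

    def test_hotspot_offset_83_fractional_count(self, query212):
        hit = _hit(query212, query212.position_of("M3", 83), len(query212))
        call = call_start(hit, query212)
        assert call.bin == "M3"
        assert call.monomer_count == pytest.approx(2 + (212 - 83 + 1) / 212)
        assert round(call.monomer_count, 3) == 2.613

    def test_tether_start_is_zero_monomers_not_averaged(self, query212):
        hit = _hit(query212, query212.position_of("T", 40), len(query212))
        call = call_start(hit, query212)
        assert call.bin == "T" and call.monomer_count == 0.0
        assert not call.averaged

    def test_outermost_monomer_goes_to_open_bin(self, query212):
        hit = _hit(query212, query212.position_of("M11", 5), len(query212))
        call = call_start(hit, query212)
        assert call.bin == "M11+"
        assert call.monomer_count > 10
        assert not call.averaged


def _call(locus, pattern="II", bin="M2", offset=1, count=2.0, averaged=True):
    return StartCall(locus, pattern, bin, offset, count, averaged)


class TestDedup:
    def test_locus_shared_between_patterns_kept_under_ii(self):
        calls = [_call("L1", "I"), _call("L1", "II")]
        (kept,) = dedup_patterns(calls)
        assert kept.pattern_id == "II"

    def test_locus_only_in_iv_stays_in_iv(self):
        (kept,) = dedup_patterns([_call("L1", "IV")])
        assert kept.pattern_id == "IV"

    def test_three_way_share_resolves_to_ii(self):
        calls = [_call("L1", "I"), _call("L1", "II"), _call("L1", "IV")]
        (kept,) = dedup_patterns(calls)
        assert kept.pattern_id == "II"

    def test_unknown_pattern_rejected(self):
        with pytest.raises(CensusError):
            dedup_patterns([_call("L1", "V")])


class TestCensus:
    def test_singleton_census(self):
        c = census([_call("L1", bin="M2", offset=1, count=2.0)], "S")
        assert c.bin_counts["M2"] == 1 and c.total == 1
        assert c.percentages["M2"] == 100.0
        assert c.average_monomer_count == pytest.approx(2.0)

    def test_partition_and_exclusions(self):
        rng = np.random.default_rng(9)
        labels = bin_labels(11)
        calls = []
        for i in range(300):
            lab = labels[int(rng.integers(len(labels)))]
            if lab == "T":
                count, averaged = 0.0, False
            elif lab == "M11+":
                count, averaged = 10.0 + rng.random(), False
            else:
                k = int(lab[1:])
                count, averaged = k - rng.random(), True
            calls.append(_call(f"L{i}", bin=lab, offset=1, count=count,
                               averaged=averaged))
        c = census(calls, "S")
        assert sum(c.bin_counts.values()) == c.total == 300
        assert c.n_averaged + c.n_excluded == 300
        assert c.n_excluded == c.bin_counts["T"] + c.bin_counts["M11+"]
        inside = [x.monomer_count for x in calls if x.averaged]
        assert c.average_monomer_count == pytest.approx(np.mean(inside))

    def test_cumulative_at_least_k_counts_complete_monomers(self):
        calls = [
            _call("a", bin="M2", offset=1, count=2.0),      # exactly 2
            _call("b", bin="M2", offset=100, count=1.5),
            _call("c", bin="M3", offset=50, count=2.7),
            _call("d", bin="M11+", offset=5, count=10.9, averaged=False),
            _call("e", bin="T", offset=3, count=0.0, averaged=False),
        ]
        c = census(calls, "S")
        assert c.cumulative[1] == (4, 80.0)
        assert c.cumulative[2] == (3, 60.0)
        assert c.cumulative[3] == (1, 20.0)
        assert c.cumulative[10] == (1, 20.0)

    def test_empty_census_has_no_divide_by_zero(self):
        c = census([], "S")
        assert c.total == 0 and math.isnan(c.average_monomer_count)
        assert all(v == 0.0 for v in c.percentages.values())

    def test_pooled_census_sums_tables(self):
        a = census([_call("a", bin="M2", count=2.0)], "A")
        b = census([_call("b", bin="M3", count=3.0),
                    _call("c", bin="M2", count=1.5)], "B")
        pooled = pooled_census([a, b])
        assert pooled.total == 3
        assert pooled.bin_counts["M2"] == 2
        assert pooled.average_monomer_count == pytest.approx(
            (2.0 + 3.0 + 1.5) / 3
        )

    def test_offset_histograms_collect_per_bin(self):
        calls = [
            _call("a", bin="M3", offset=83, count=2.6),
            _call("b", bin="M3", offset=83, count=2.6),
            _call("c", bin="M3", offset=86, count=2.6),
        ]
        c = census(calls, "S")
        assert c.offset_histograms["M3"] == {83: 2, 86: 1}


class TestPercent:
    @pytest.mark.parametrize(
        "n,d,expected",
        [
            (3515, 5765, 61.0),
            (357, 1125, 31.7),
            (667, 931, 71.6),
            (1032, 1125, 91.7),
            (26, 157, 16.6),
            (94, 357, 26.3),
            (0, 100, 0.0),
        ],
    )
    def test_reporting_examples(self, n, d, expected):
        assert percent(n, d) == expected

    def test_rounds_half_away_from_zero(self):
        assert percent(1, 2000) == 0.1  # 0.05 -> 0.1, not banker's 0.0
        assert percent(25, 1000) == 2.5

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(CensusError):
            percent(5, 0)


class TestPairwiseIdentity:
    def test_monomer_divergence_examples(self):
        a = "A" * 208
        b = "A" * 180 + "C" * 28
        assert pairwise_identity(a, b) == (180, 208, 86.5)
        a2 = "G" * 214
        b2 = "G" * 164 + "T" * 50
        assert pairwise_identity(a2, b2) == (164, 214, 76.6)

    def test_identical_sequences(self):
        assert pairwise_identity("A" * 50, "A" * 50) == (50, 50, 100.0)

    def test_gap_columns_count_but_never_match(self):
        ident, cols, pct = pairwise_identity("AC-GT", "ACCGT")
        assert (ident, cols) == (4, 5)
        ident2, _, _ = pairwise_identity("AC-GT", "AC-GT")
        assert ident2 == 4  # the shared gap column is not an identity

    def test_unequal_lengths_rejected(self):
        with pytest.raises(CensusError):
            pairwise_identity("ACGT", "ACG")


def points_with_correlation(r, n, seed=0, x=None):
    """Engineer n points whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x if x is not None else rng.random(n), dtype=float)
    zx = (x - x.mean()) / x.std()
    e = rng.standard_normal(n)
    e -= e.mean()
    e -= zx * (e @ zx) / (zx @ zx)
    e /= np.sqrt((e ** 2).mean())
    y = r * zx + math.sqrt(1 - r * r) * e
    return list(zip(x.tolist(), y.tolist()))


class TestRegression:
    def test_age_trend_p_value_matches_printed_precision(self):
        """Seven subfamily points with r = -0.91 give a two-sided slope
        p-value of 0.004 at three decimals (t on 5 df)."""
        points = points_with_correlation(-0.91, 7, seed=1)
        fit = age_regression(points)
        assert fit.r == pytest.approx(-0.91, abs=1e-9)
        assert round(fit.p, 3) == 0.004
        assert fit.p == pytest.approx(correlation_pvalue(-0.91, 7), rel=1e-9)

    def test_collinear_points_give_perfect_negative_correlation(self):
        points = [(x, 10.0 - 2.0 * x) for x in (0.2, 0.5, 1.1, 1.8, 2.2)]
        fit = age_regression(points)
        assert fit.r == pytest.approx(-1.0)
        assert fit.p < 1e-10

    def test_matches_normal_equations_oracle(self):
        points = [(0.21, 3.7), (0.45, 3.5), (0.75, 2.3),
                  (1.3, 2.5), (2.15, 1.5)]
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        n = len(points)
        sxx = (x ** 2).sum() - x.sum() ** 2 / n
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        syy = (y ** 2).sum() - y.sum() ** 2 / n
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r = sxy / math.sqrt(sxx * syy)
        fit = age_regression(points)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r == pytest.approx(r)
        assert fit.p == pytest.approx(correlation_pvalue(r, n), rel=1e-9)

    def test_insufficient_or_degenerate_input(self):
        with pytest.raises(CensusError):
            age_regression([(1, 2), (2, 3)])
        with pytest.raises(CensusError):
            age_regression([(1, 2), (1, 3), (1, 4)])
        with pytest.raises(CensusError):
            age_regression([(1, 2), (1, 3), (2, 4)])  # duplicate age
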