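"""Inside/outside classification, split-ratio estimation, consensus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splitmap as sm


def wilson_interval(k, n, z=1.959963984540054):
    """Independent closed-form Wilson score interval oracle."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestClassifyPair:
    def test_worked_example_is_inside(self, hpr_counts):
        call = sm.classify_pair(hpr_counts)
        assert call.verdict == "inside"
        assert call.unmarked_fraction == 0.0

    def test_common_unmarked_with_left_loss_majority_points_right(self):
        # more progeny lost the left marker than the right: lesion right of pair
        c = sm.ProgenyCounts("R,D", n_lost_left=18, n_lost_right=5, n_unmarked=12)
        assert sm.classify_pair(c).verdict == "outside_right"

    def test_common_unmarked_with_right_loss_majority_points_left(self):
        c = sm.ProgenyCounts("Sb,H", n_lost_left=1, n_lost_right=12, n_unmarked=10)
        assert sm.classify_pair(c).verdict == "outside_left"

    def test_tied_splits_ambiguous(self):
        c = sm.ProgenyCounts("Sb,H", n_lost_left=8, n_lost_right=8, n_unmarked=10)
        assert sm.classify_pair(c).verdict == "ambiguous"

    def test_below_min_informative_is_ambiguous_not_error(self):
        c = sm.ProgenyCounts("Sb,H", n_lost_left=2, n_lost_right=1, n_unmarked=1)
        call = sm.classify_pair(c)
        assert call.verdict == "ambiguous"
        assert "score more progeny" in call.support_note

    def test_absolute_rarity_criterion(self):
        # one unmarked among few splits: fraction high but count <= k0
        c = sm.ProgenyCounts("H,Pr", n_lost_left=6, n_lost_right=5, n_unmarked=1)
        assert sm.classify_pair(c).verdict == "inside"

    def test_direction_significance_gate(self):
        config = sm.ClassifyConfig(require_significant_direction=True)
        weak = sm.ProgenyCounts("R,D", n_lost_left=8, n_lost_right=6, n_unmarked=10)
        strong = sm.ProgenyCounts("R,D", n_lost_left=24, n_lost_right=4, n_unmarked=10)
        assert sm.classify_pair(weak, config).verdict == "ambiguous"
        assert sm.classify_pair(strong, config).verdict == "outside_right"


class TestEstimateWithinPair:
    def test_worked_example_point(self, chr3, hpr_counts):
        est = sm.estimate_within_pair(hpr_counts, chr3.pair("H,Pr"))
        assert est.cM_point == 80.1

    def test_zero_lost_left_pins_to_left_marker(self, chr3):
        c = sm.ProgenyCounts("H,Pr", n_lost_left=0, n_lost_right=9, n_unmarked=0)
        est = sm.estimate_within_pair(c, chr3.pair("H,Pr"))
        assert est.cM_point == pytest.approx(69.5)

    def test_equal_splits_give_midpoint(self, chr3):
        c = sm.ProgenyCounts("H,Pr", n_lost_left=9, n_lost_right=9, n_unmarked=0)
        est = sm.estimate_within_pair(c, chr3.pair("H,Pr"))
        assert est.cM_point == pytest.approx((69.5 + 90.0) / 2, abs=0.05)

    def test_zero_splits_is_estimation_error(self, chr3):
        c = sm.ProgenyCounts("H,Pr", n_lost_left=0, n_lost_right=0, n_unmarked=0)
        with pytest.raises(sm.EstimationError, match="more progeny"):
            sm.estimate_within_pair(c, chr3.pair("H,Pr"))

    @pytest.mark.parametrize("k,n", [(14, 27), (1, 30), (29, 30), (10, 20)])
    def test_wilson_bounds_match_closed_form(self, chr3, k, n):
        pair = chr3.pair("H,Pr")
        c = sm.ProgenyCounts("H,Pr", n_lost_left=k, n_lost_right=n - k, n_unmarked=0)
        est = sm.estimate_within_pair(c, pair)
        lo_f, hi_f = wilson_interval(k, n)
        span = pair.span_cM
        assert est.cM_low == pytest.approx(
            max(pair.left.cM, min(est.cM_point, pair.left.cM + lo_f * span)), abs=1e-6
        )
        assert est.cM_high == pytest.approx(
            min(pair.right.cM, max(est.cM_point, pair.left.cM + hi_f * span)), abs=1e-6
        )

    def test_interval_brackets_point_and_pair(self, chr3):
        pair = chr3.pair("Sb,H")
        c = sm.ProgenyCounts("Sb,H", n_lost_left=2, n_lost_right=30, n_unmarked=0)
        est = sm.estimate_within_pair(c, pair)
        assert pair.left.cM <= est.cM_low <= est.cM_point <= est.cM_high <= pair.right.cM

    @given(
        nl=st.integers(min_value=0, max_value=80),
        delta=st.integers(min_value=1, max_value=40),
        nr=st.integers(min_value=0, max_value=80),
    )
    @settings(derandomize=True, max_examples=200)
    def test_point_monotone_in_lost_left(self, chr3, nl, delta, nr):
        """Increasing the lost-left count never moves the estimate leftward."""
        pair = chr3.pair("H,Pr")
        a = sm.ProgenyCounts("H,Pr", n_lost_left=nl, n_lost_right=nr, n_unmarked=0)
        b = sm.ProgenyCounts("H,Pr", n_lost_left=nl + delta, n_lost_right=nr, n_unmarked=0)
        if a.n_splits == 0:
            return
        assert (
            sm.estimate_within_pair(a, pair).cM_point
            <= sm.estimate_within_pair(b, pair).cM_point
        )


def call(pair_id, verdict, u=0.3):
    return sm.PairCall(pair_id=pair_id, verdict=verdict, unmarked_fraction=u)


def est_for(chr3, pair_id, counts):
    return sm.estimate_within_pair(counts, chr3.pair(pair_id))


class TestConsensus:
    def test_worked_example_localizes(self, chr3, hpr_counts):
        results = [
            (call("R,D", "outside_right"), None),
            (call("Gl,Sb", "outside_right"), None),
            (call("Sb,H", "outside_right"), None),
            (call("H,Pr", "inside", u=0.0), est_for(chr3, "H,Pr", hpr_counts)),
        ]
        res = sm.consensus(results, chr3)
        assert res.status == "localized"
        assert res.estimate.cM_point == 80.1
        assert not res.conflicts

    def test_all_outside_left_is_terminal_left(self, chr3):
        results = [
            (call(pid, "outside_left"), None) for pid in ("R,D", "Gl,Sb", "Sb,H", "H,Pr")
        ]
        res = sm.consensus(results, chr3)
        assert res.status == "terminal_left"
        assert res.region == "left of R"

    def test_all_outside_right_is_terminal_right(self, chr3):
        results = [(call(pid, "outside_right"), None) for pid in ("R,D", "Sb,H")]
        res = sm.consensus(results, chr3)
        assert res.status == "terminal_right"
        assert res.region == "right of Pr"

    def test_bracketing_directions_name_gap_flanks(self, chr3):
        results = [
            (call("R,D", "outside_right"), None),
            (call("Sb,H", "outside_left"), None),
            (call("H,Pr", "outside_left"), None),
        ]
        res = sm.consensus(results, chr3)
        assert res.status == "gap_region"
        assert res.region == "between D and Sb"

    def test_two_inside_calls_inconsistent_with_shared_marker_note(self, chr3):
        ca = sm.ProgenyCounts("Sb,H", n_lost_left=10, n_lost_right=10, n_unmarked=0)
        cb = sm.ProgenyCounts("H,Pr", n_lost_left=10, n_lost_right=10, n_unmarked=0)
        results = [
            (call("Sb,H", "inside", u=0.0), est_for(chr3, "Sb,H", ca)),
            (call("H,Pr", "inside", u=0.0), est_for(chr3, "H,Pr", cb)),
        ]
        res = sm.consensus(results, chr3)
        assert res.status == "inconsistent"
        assert any("share marker H" in c for c in res.conflicts)

    def test_contradicted_inside_is_inconsistent(self, chr3, hpr_counts):
        # an outside call pointing right of Pr excludes an 80.1 cM estimate
        results = [
            (call("H,Pr", "inside", u=0.0), est_for(chr3, "H,Pr", hpr_counts)),
            (call("Sb,H", "outside_left"), None),
        ]
        res = sm.consensus(results, chr3)
        assert res.status == "inconsistent"
        assert res.conflicts

    def test_crossing_directions_inconsistent(self, chr3):
        results = [
            (call("Sb,H", "outside_right"), None),
            (call("R,D", "outside_left"), None),
        ]
        res = sm.consensus(results, chr3)
        assert res.status == "inconsistent"
        assert res.conflicts

    def test_empty_input_rejected(self, chr3):
        with pytest.raises(ValueError):
            sm.consensus([], chr3)

    def test_all_ambiguous_flagged(self, chr3):
        res = sm.consensus([(call("Sb,H", "ambiguous"), None)], chr3)
        assert res.status == "inconsistent"
        assert "no informative pair calls" in res.conflicts

    def test_edge_pinned_inside_with_unanimous_left_directions_is_terminal(self, chr3):
        # a lesion beyond R produces almost no unmarked progeny in the R,D
        # cross; the unanimous leftward direction of the other pairs makes
        # the terminal call
        c = sm.ProgenyCounts("R,D", n_lost_left=0, n_lost_right=40, n_unmarked=0)
        results = [
            (call("R,D", "inside", u=0.01), est_for(chr3, "R,D", c)),
            (call("Gl,Sb", "outside_left"), None),
            (call("Sb,H", "outside_left"), None),
        ]
        res = sm.consensus(results, chr3)
        assert res.status == "terminal_left"
        assert res.region == "left of R"


class TestStochasticCalibration:
    def test_wilson_interval_covers_large_sample_target(self, chr3):
        """Coverage of the closed-form split-ratio target at nominal 95%."""
        pair = chr3.pair("H,Pr")
        design = sm.CrossDesign(chromosome=chr3, pair=pair, lethal_cM=(80.13,))
        exp = sm.expected_class_frequencies(design)
        f = exp["lost_left"] / (exp["lost_left"] + exp["lost_right"])
        target = pair.left.cM + f * pair.span_cM
        rng = np.random.default_rng(314)
        covered = 0
        reps = 100
        for _ in range(reps):
            counts = sm.simulate_scored(design, 2000, rng=rng)
            est = sm.estimate_within_pair(counts, pair)
            covered += est.cM_low <= target <= est.cM_high
        assert covered / reps >= 0.90

    def test_inside_call_rate_over_position_grid(self, chr3):
        """A lesion >= 2 cM inside a pair is called inside at vial scale.

        Among decided (non-ambiguous) calls the inside rate per grid point
        must reach 0.925 (= 0.95 minus a one-sided 95% binomial allowance
        at 200 replicates) for pairs up to ~20 cM, and 0.80 for the ~40 cM
        R,D pair, whose double-crossover unmarked class is no longer rare
        at vial scale — the wide-pair resolution cost on the left arm.
        Narrow pairs may abstain (too few informative progeny) in a small
        fraction of vials rather than misclassify.
        """
        rng = np.random.default_rng(2718)
        reps = 200
        for pair_id in ("R,D", "Gl,Sb", "Sb,H", "H,Pr"):
            pair = chr3.pair(pair_id)
            grid = [
                pair.left.cM + 2.0,
                0.5 * (pair.left.cM + pair.right.cM),
                pair.right.cM - 2.0,
            ]
            floor = 0.80 if pair.span_cM > 25 else 0.925
            for pos in grid:
                design = sm.CrossDesign(chromosome=chr3, pair=pair, lethal_cM=(pos,))
                verdicts = [
                    sm.classify_pair(sm.simulate_scored(design, 150, rng=rng)).verdict
                    for _ in range(reps)
                ]
                decided = [v for v in verdicts if v != "ambiguous"]
                assert len(decided) >= 0.85 * reps, (pair_id, pos)
                inside = sum(v == "inside" for v in decided)
                assert inside / len(decided) >= floor, (pair_id, pos, inside)
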