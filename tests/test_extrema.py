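"""Extremum candidates, the disambiguation cascade, and finalization."""

import numpy as np
import pytest

from inclinegait.extrema import (
    ExtremumCandidate,
    apply_cascade,
    finalize,
    find_candidates,
    locate_extrema,
)
from inclinegait.normalization import gaussian_filter_curve
from tests.conftest import make_curve, m_curve


def cand(index, polarity, value, dist=5):
    return ExtremumCandidate(
        index=index, polarity=polarity, filtered_value=value, monotony_distance=dist
    )


class TestFindCandidates:
    def test_ideal_m_curve_has_two_maxima_one_minimum(self, clean_m_curve):
        cands = find_candidates(clean_m_curve)
        maxima = [c for c in cands if c.polarity == "max"]
        minima = [c for c in cands if c.polarity == "min"]
        assert [c.index for c in maxima] == [25, 75]
        assert [c.index for c in minima] == [50]
        assert all(c.monotony_distance == 5 for c in cands)

    def test_strictly_monotone_curve_has_no_candidates(self):
        assert find_candidates(np.linspace(0, 1, 100)) == []

    def test_plateau_peak_yields_no_strict_candidate(self):
        v = np.concatenate([np.linspace(0, 1, 40), np.full(20, 1.0), np.linspace(1, 0, 40)])
        assert find_candidates(v) == []

    def test_monotony_distance_truncated_by_short_runs(self):
        # maximum at 50 with a shoulder 2 steps down on the right
        v = np.zeros(100)
        v[:51] = np.linspace(0, 1, 51)
        v[51] = 0.95
        v[52] = 0.96  # reversal two steps after the peak
        v[53:] = np.linspace(0.96, 0.0, 47)
        cands = find_candidates(v)
        peak = next(c for c in cands if c.index == 50)
        assert peak.monotony_distance == 1

    def test_endpoints_are_never_candidates(self):
        v = np.zeros(100)
        v[0] = 2.0
        v[99] = 2.0
        v[1:99] = 1.0
        assert all(1 <= c.index <= 98 for c in find_candidates(v))


class TestCascade:
    def test_conclusive_input_passes_untouched(self):
        cands = [cand(25, "max", 1.2, 2), cand(50, "min", 0.9, 1), cand(75, "max", 1.1, 0)]
        assert apply_cascade(cands) == cands

    def test_edge_candidates_eliminated_by_time_plausibility(self):
        cands = [
            cand(5, "max", 2.0),
            cand(25, "max", 1.2),
            cand(50, "min", 0.9),
            cand(75, "max", 1.1),
            cand(95, "min", 0.1),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv] == [25, 50, 75]

    def test_pool_keeps_highest_force_maximum(self):
        cands = [
            cand(40, "max", 1.18),
            cand(43, "max", 1.21),
            cand(55, "min", 0.9),
            cand(75, "max", 1.1),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv if c.polarity == "max"] == [43, 75]

    def test_pool_chains_span_by_single_linkage(self):
        # 20-24-28 pairwise gaps of 4 chain into one pool
        cands = [
            cand(20, "max", 1.0),
            cand(24, "max", 1.3),
            cand(28, "max", 1.1),
            cand(50, "min", 0.8),
            cand(75, "max", 1.2),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv if c.polarity == "max"] == [24, 75]

    def test_pool_tie_broken_by_earlier_index(self):
        cands = [
            cand(40, "max", 1.2),
            cand(43, "max", 1.2),
            cand(55, "min", 0.9),
            cand(75, "max", 1.1),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv if c.polarity == "max"] == [40, 75]

    def test_monotony_check_drops_weak_candidates(self):
        cands = [
            cand(25, "max", 1.2, 5),
            cand(35, "max", 1.0, 2),
            cand(50, "min", 0.9, 5),
            cand(75, "max", 1.1, 5),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv] == [25, 50, 75]

    def test_grace_reinstates_best_monotony_first(self):
        # monotony check leaves one maximum; grace restores the stronger
        # of the casualties (distance 4 beats distance 2)
        cands = [
            cand(25, "max", 1.2, 4),
            cand(45, "min", 0.9, 5),
            cand(60, "max", 1.0, 2),
            cand(75, "max", 1.1, 5),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv if c.polarity == "max"] == [25, 75]

    def test_grace_reinstates_minimum_when_none_survive(self):
        cands = [
            cand(25, "max", 1.2, 5),
            cand(50, "min", 0.9, 3),
            cand(60, "min", 0.95, 1),
            cand(75, "max", 1.1, 5),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv if c.polarity == "min"] == [50]

    def test_grace_tie_prefers_stronger_filtered_force(self):
        cands = [
            cand(22, "max", 1.0, 2),
            cand(30, "max", 1.05, 5),
            cand(49, "min", 0.85, 5),
            cand(70, "max", 1.2, 2),
        ]
        surv = apply_cascade(cands)
        assert [c.index for c in surv if c.polarity == "max"] == [30, 70]

    def test_cascade_is_deterministic(self):
        rng = np.random.default_rng(0)
        v = m_curve() + rng.normal(0, 0.02, 100)
        c1 = apply_cascade(find_candidates(v), v)
        c2 = apply_cascade(find_candidates(v), v)
        assert c1 == c2


class TestFinalize:
    def test_accepts_ordered_survivors_and_rereads_unfiltered_values(self, clean_m_curve):
        curve = make_curve(clean_m_curve)
        res = finalize(
            [cand(25, "max", 1.19), cand(52, "min", 0.89), cand(76, "max", 1.15)],
            curve,
        )
        assert res.accepted
        assert (res.fz2_index, res.fz3_index, res.fz4_index) == (25, 52, 76)
        assert res.fz2 == curve.values[25]
        assert res.fz4 == curve.values[76]

    def test_three_maxima_rejected_for_candidate_count(self, clean_m_curve):
        res = finalize(
            [
                cand(20, "max", 1.0),
                cand(40, "max", 1.1),
                cand(60, "min", 0.9),
                cand(80, "max", 1.0),
            ],
            make_curve(clean_m_curve),
        )
        assert res.status == "rejected" and res.reason == "candidate_count"

    def test_minimum_outside_maxima_rejected_for_ordering(self, clean_m_curve):
        res = finalize(
            [cand(25, "max", 1.2), cand(40, "max", 1.1), cand(70, "min", 0.9)],
            make_curve(clean_m_curve),
        )
        assert res.status == "rejected" and res.reason == "ordering"

    def test_ordering_requirement_can_be_disabled(self, clean_m_curve):
        res = finalize(
            [cand(25, "max", 1.2), cand(40, "max", 1.1), cand(70, "min", 0.9)],
            make_curve(clean_m_curve),
            require_ordering=False,
        )
        assert res.accepted


class TestEndToEnd:
    def test_noiseless_m_curve_cascade_is_noop_and_indices_exact(self, clean_m_curve):
        curve = make_curve(clean_m_curve)
        filtered = gaussian_filter_curve(curve)
        cands = find_candidates(filtered)
        assert apply_cascade(cands, filtered) == cands
        res = locate_extrema(curve, filtered)
        assert res.accepted
        assert abs(res.fz2_index - 25) <= 2
        assert abs(res.fz3_index - 50) <= 2
        assert abs(res.fz4_index - 75) <= 2
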