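"""Six-pattern classification, Yin/Yang summaries and dose trends."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synchrometab.yinyang import (ChangePair, classify, classify_pattern,
                                  compute_changes, dose_trend, summarize,
                                  vehicle_yinyang, yinyang_of, PATTERNS)
from conftest import make_study

# one representative point per region of the (v1, v2) plane
REGION_POINTS = {
    "PT": (-0.5, 0.3),
    "NT": (0.4, -0.2),
    "PA": (0.3, 0.8),
    "PR": (0.8, 0.3),
    "NA": (-0.8, -0.3),
    "NR": (-0.3, -0.8),
    "NC": (0.0, 0.4),
}

ANTISYMMETRY = {"PT": "NT", "NT": "PT", "PA": "NR", "NR": "PA",
                "NA": "PR", "PR": "NA", "NC": "NC"}


class TestClassify:
    @pytest.mark.parametrize("expected,point", sorted(REGION_POINTS.items()))
    def test_region_representatives(self, expected, point):
        assert classify(*point) == expected

    def test_direction_labels(self):
        assert yinyang_of("PT") == yinyang_of("PA") == yinyang_of("NA") == "Yang"
        assert yinyang_of("NT") == yinyang_of("PR") == yinyang_of("NR") == "Yin"
        assert yinyang_of("NC") == "neutral"

    def test_exhaustive_sign_order_enumeration(self):
        # all sign/order combinations on a 5-value grid: the classifier
        # must agree with the region definitions point by point
        grid = [-2.0, -1.0, 0.0, 1.0, 2.0]
        for v1, v2 in itertools.product(grid, repeat=2):
            got = classify(v1, v2)
            if v1 == 0 or v2 == 0 or v1 == v2:
                assert got == "NC"
            elif v1 < 0 < v2:
                assert got == "PT"
            elif v2 < 0 < v1:
                assert got == "NT"
            elif 0 < v1 < v2:
                assert got == "PA"
            elif 0 < v2 < v1:
                assert got == "PR"
            elif v1 < v2 < 0:
                assert got == "NA"
            else:
                assert got == "NR"

    @given(st.floats(-10, 10, allow_nan=False),
           st.floats(-10, 10, allow_nan=False))
    @settings(derandomize=True, max_examples=300)
    def test_total_partition(self, v1, v2):
        assert classify(v1, v2) in PATTERNS

    def test_antisymmetry_under_global_sign_flip(self):
        for pattern, (v1, v2) in REGION_POINTS.items():
            assert classify(-v1, -v2) == ANTISYMMETRY[pattern]

    def test_assignment_carries_direction(self):
        a = classify_pattern(ChangePair("m", -0.5, 0.3, "DH1"))
        assert (a.pattern, a.yinyang) == ("PT", "Yang")
        with pytest.raises(ValueError):
            ChangePair("m", math.nan, 0.3, "DH1")


class TestComputeChanges:
    def _study(self, sham, vehicle, dh1):
        return make_study(
            {"m": [*sham, *vehicle, *dh1]},
            {"sham": ["s1", "s2"], "vehicle": ["v1", "v2"],
             "DH1": ["d1", "d2"]})

    def test_equal_means_snap_to_zero(self):
        pairs = compute_changes(self._study([4, 4], [4, 4], [4, 4]))
        assert pairs[0].v1 == 0.0 and pairs[0].v2 == 0.0

    def test_doubling_gives_log2_one(self):
        pairs = compute_changes(self._study([2, 2], [4, 4], [4, 4]))
        assert pairs[0].v1 == 1.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            compute_changes(self._study([0, 0], [4, 4], [4, 4]))

    def test_planted_shifts_recovered(self, default_study, default_truth):
        cfg = default_truth.generating_parameters
        pairs = compute_changes(default_study)
        # planted PT in DH1 has v1 = -effect_size, v2 = +effect_size/4
        pt_dh1 = [m for (m, g), p in default_truth.true_patterns.items()
                  if g == "DH1" and p == "PT"]
        by_key = {(p.metabolite, p.group): p for p in pairs}
        for m in pt_dh1:
            p = by_key[(m, "DH1")]
            assert p.v1 == pytest.approx(-cfg.effect_size, abs=0.2)
            assert p.v2 == pytest.approx(cfg.effect_size / 4, abs=0.2)


class TestSummarize:
    def _assign(self, pattern_counts, group="DH1"):
        out = []
        i = 0
        for pattern, c in pattern_counts.items():
            for _ in range(c):
                out.append(classify_pattern(
                    ChangePair(f"m{i}", *REGION_POINTS[pattern], group)))
                i += 1
        return out

    def test_ratio_and_difference_arithmetic(self):
        s = summarize(self._assign({"PT": 10, "NT": 5}), "DH1")
        assert s.separate_ratio == 2.0
        assert s.separate_difference == 5

    def test_balanced_counts(self):
        s = summarize(self._assign({p: 2 for p in
                                    ("PT", "NT", "PA", "PR", "NA", "NR")}),
                      "DH1")
        assert s.overall_ratio == 1.0
        assert s.overall_difference == 0

    def test_counts_total_and_zero_denominator(self):
        s = summarize(self._assign({"PT": 3, "NC": 2}), "DH1")
        assert sum(s.counts.values()) == 5
        assert s.separate_ratio == math.inf

    def test_wrong_group_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._assign({"PT": 1}, group="DH2"), "DH1")

    def test_planted_counts_recovered(self, default_study, default_truth):
        pairs = compute_changes(default_study)
        assignments = [classify_pattern(p) for p in pairs
                       if p.group == "DH4"]
        s = summarize(assignments, "DH4")
        truth_counts = {p: 0 for p in PATTERNS}
        for (m, g), p in default_truth.true_patterns.items():
            if g == "DH4":
                truth_counts[p] += 1
        for p in ("PT", "NT", "PA", "PR", "NA", "NR"):
            assert abs(s.counts[p] - truth_counts[p]) <= 1

    def test_yang_yin_nc_partition_total(self, default_study):
        pairs = compute_changes(default_study)
        for g in ("DH1", "DH2", "DH3", "DH4"):
            s = summarize([classify_pattern(p) for p in pairs
                           if p.group == g], g)
            assert s.yang_total + s.yin_total + s.counts["NC"] == 41


class TestVehicleYinyang:
    def test_signs(self):
        study = make_study(
            {"up": [1, 1, 2, 2], "down": [4, 4, 2, 2], "flat": [3, 3, 3, 3]},
            {"sham": ["s1", "s2"], "vehicle": ["v1", "v2"]})
        states = vehicle_yinyang(study)
        assert states == {"up": "Yang", "down": "Yin", "flat": "neutral"}

    def test_planted_two_thirds_yin(self, default_study):
        states = vehicle_yinyang(default_study)
        yin = sum(1 for v in states.values() if v == "Yin")
        assert yin / len(states) == pytest.approx(2 / 3, abs=0.05)


class TestDoseTrend:
    def test_exact_line(self):
        tr = dose_trend({"DH1": 8, "DH2": 6, "DH3": 4, "DH4": 2}, axis="rank")
        assert tr.r == pytest.approx(-1.0)
        assert tr.slope == pytest.approx(-2.0)

    def test_constant_counts_flagged(self):
        tr = dose_trend({"DH1": 5, "DH2": 5, "DH3": 5}, axis="rank")
        assert not tr.defined and math.isnan(tr.r) and tr.slope == 0.0

    def test_matches_direct_pearson_formula(self):
        counts = {"DH1": 3, "DH2": 5, "DH3": 4, "DH4": 8}
        tr = dose_trend(counts, axis="rank")
        x = np.array([1, 2, 3, 4], dtype=float)
        y = np.array([3, 5, 4, 8], dtype=float)
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert tr.r == pytest.approx(r, abs=1e-12)

    def test_dose_axes(self):
        counts = {"DH1": 2, "DH2": 4, "DH3": 6, "DH4": 7}
        doses = {"DH1": 1, "DH2": 2.5, "DH3": 5, "DH4": 10}
        for axis in ("dose", "log2dose"):
            tr = dose_trend(counts, axis=axis, dose_levels=doses)
            assert tr.axis == axis and tr.r > 0.9

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            dose_trend({"DH1": 1, "DH2": 2}, axis="rank")
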