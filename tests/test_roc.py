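"""ROC machinery: curve construction, corner criterion, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import gaitcounts as gc
from gaitcounts.errors import (
    DegenerateCurveError,
    DegenerateLabelsError,
    InsufficientClassesError,
)
from gaitcounts.roc import (
    CutPointTable,
    RocCurve,
    build_cutpoint_table,
    category_performance,
    grade_auc,
    optimal_cutpoint,
    roc_curve,
)
from gaitcounts.synthetic import generate_cohort


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise concordance oracle: U / (n1 * n2)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    u = sum(1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg))
    return u / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_four_point_oracle_example(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(
            mann_whitney_auc([1, 2, 3, 4], [0, 0, 1, 1]))
        assert curve.auc == pytest.approx(1.0)

    def test_chance_level_in_expectation(self, rng):
        aucs = []
        for _ in range(200):
            s = rng.normal(size=60)
            y = rng.integers(0, 2, size=60)
            if 0 < y.sum() < 60:
                aucs.append(roc_curve(s, y).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_endpoints_cover_both_corners(self, rng):
        curve = roc_curve(rng.normal(size=50), rng.integers(0, 2, size=50))
        assert curve.sensitivity[0] == 0 and curve.specificity[0] == 1
        assert curve.sensitivity[-1] == 1 and curve.specificity[-1] == 0

    def test_monotone_operating_points(self, rng):
        curve = roc_curve(rng.normal(size=100), rng.integers(0, 2, size=100))
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(1.0 - curve.specificity) >= 0)

    def test_matches_mann_whitney_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            s = rng.integers(0, 20, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            assert roc_curve(s, y).auc == pytest.approx(
                mann_whitney_auc(s, y), abs=1e-9)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            s = rng.normal(size=150)
            y = rng.integers(0, 2, size=150)
            if y.sum() in (0, 150):
                continue
            assert roc_curve(s, y).auc == pytest.approx(
                roc_auc_score(y, s), abs=1e-12)


class TestOptimalCutpoint:
    def test_perfect_classes_attain_the_corner(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        _, sens, spec = optimal_cutpoint(curve)
        assert sens == 1.0 and spec == 1.0

    def test_constructed_three_point_curve(self):
        # distances to (1,1): sqrt(.17), sqrt(.08), sqrt(.2525) -> middle wins
        curve = RocCurve(
            thresholds=np.array([3.0, 2.0, 1.0]),
            sensitivity=np.array([0.6, 0.8, 0.95]),
            specificity=np.array([0.9, 0.8, 0.5]),
            auc=0.8,
        )
        t, sens, spec = optimal_cutpoint(curve)
        assert (t, sens, spec) == (2.0, 0.8, 0.8)

    def test_tie_broken_by_higher_sensitivity(self):
        curve = RocCurve(
            thresholds=np.array([3.0, 2.0]),
            sensitivity=np.array([0.6, 0.8]),
            specificity=np.array([0.8, 0.6]),
            auc=0.7,
        )
        _, sens, _ = optimal_cutpoint(curve)
        assert sens == 0.8

    def test_degenerate_curve_rejected(self):
        curve = RocCurve(thresholds=np.array([np.inf]),
                         sensitivity=np.array([0.0]),
                         specificity=np.array([1.0]), auc=0.5)
        with pytest.raises(DegenerateCurveError):
            optimal_cutpoint(curve)

    def test_gaussian_threshold_recovery(self):
        # equal-variance classes: the corner-criterion limit is the midpoint
        rng = np.random.default_rng(0)
        neg = rng.normal(0.0, 1.0, 10_000)
        pos = rng.normal(2.0, 1.0, 10_000)
        scores = np.concatenate([neg, pos])
        labels = np.concatenate([np.zeros(10_000), np.ones(10_000)])
        t, _, _ = optimal_cutpoint(roc_curve(scores, labels))
        assert abs(t - 1.0) / 2.0 < 0.02  # within 2% of the class gap

    def test_null_distribution_selects_interior_points(self, rng):
        sens, spec = [], []
        for _ in range(100):
            s = rng.normal(size=200)
            y = rng.integers(0, 2, size=200)
            if y.sum() in (0, 200):
                continue
            _, se, sp = optimal_cutpoint(roc_curve(s, y))
            sens.append(se)
            spec.append(sp)
        assert 0.3 <= np.mean(sens) <= 0.7
        assert 0.3 <= np.mean(spec) <= 0.7


class TestGrading:
    @pytest.mark.parametrize("auc, grade", [
        (0.60, "poor"), (0.69, "poor"), (0.70, "fair"), (0.79, "fair"),
        (0.80, "good"), (0.85, "good"), (0.89, "good"), (0.90, "excellent"),
        (0.99, "excellent"), (1.0, "perfect"),
    ])
    def test_bands(self, auc, grade):
        assert grade_auc(auc) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade_auc(1.2)

    @given(a=st.floats(min_value=0, max_value=1),
           b=st.floats(min_value=0, max_value=1))
    def test_grading_is_monotone_step_function(self, a, b):
        order = {g: i for i, g in enumerate(
            ["poor", "fair", "good", "excellent", "perfect"])}
        lo, hi = min(a, b), max(a, b)
        assert order[grade_auc(lo)] <= order[grade_auc(hi)]


def _separable_table():
    """Cohort whose category count ranges do not overlap at all."""
    rng = np.random.default_rng(3)
    rows = []
    ranges = {0: (0, 100), 1: (200, 400), 2: (600, 800), 3: (1000, 1500)}
    for cat, (lo, hi) in ranges.items():
        for _ in range(40):
            vm = int(rng.integers(lo, hi))
            rows.append({"placement": "waist", "filter_mode": "default",
                         "epoch_length_s": 15, "category": cat,
                         "count_v": vm // 2, "count_vm": vm})
    import pandas as pd
    return pd.DataFrame(rows), ranges


class TestCalibration:
    def test_separable_boundaries_fall_between_classes(self):
        table, ranges = _separable_table()
        cuts, curves = build_cutpoint_table(table, "waist")
        assert ranges[0][1] <= cuts.t1 < ranges[1][0]
        assert ranges[1][1] <= cuts.t2 < ranges[2][0]
        assert ranges[2][1] <= cuts.t3 < ranges[3][0]
        assert all(c.auc == 1.0 for c in curves.values())

    def test_missing_category_rejected(self):
        table, _ = _separable_table()
        with pytest.raises(InsufficientClassesError):
            build_cutpoint_table(table[table.category != 2], "waist")

    def test_boundaries_strictly_increase_on_noisy_data(self):
        for seed in range(5):
            cohort = generate_cohort(gc.SimConfig(n_participants=6,
                                                  seed=700 + seed))
            for placement in ("waist", "ankle"):
                cuts, _ = build_cutpoint_table(cohort, placement)
                assert cuts.t1 < cuts.t2 < cuts.t3

    def test_adjacent_pair_scheme_available(self):
        table, ranges = _separable_table()
        cuts, _ = build_cutpoint_table(table, "waist", scheme="adjacent")
        assert ranges[0][1] <= cuts.t1 < ranges[1][0]
        assert ranges[2][1] <= cuts.t3 < ranges[3][0]

    def test_recovered_boundaries_bracketed_by_class_medians(self):
        hits = 0
        for seed in range(5):
            cohort = generate_cohort(gc.SimConfig(n_participants=42,
                                                  seed=2000 + seed))
            cuts, _ = build_cutpoint_table(cohort, "waist")
            if cuts.t1 < 519 < cuts.t2 < 759 < cuts.t3 < 1147:
                hits += 1
        assert hits >= 4


class TestCategoryPerformance:
    def test_perfect_separation_gives_unit_rates(self):
        table, _ = _separable_table()
        cuts, _ = build_cutpoint_table(table, "waist")
        perf = category_performance(table, cuts)
        for sens, spec in perf.values():
            assert sens == 1.0 and spec == 1.0

    def test_constructed_failure_has_zero_sensitivity(self):
        import pandas as pd
        cuts = CutPointTable(placement="waist", axis="vm", epoch_length_s=15,
                             t1=100, t2=200, t3=300)
        # every SLOW epoch's count lands in the MED interval (201..300)
        table = pd.DataFrame({
            "placement": "waist", "epoch_length_s": 15,
            "category": [1] * 10 + [0] * 10,
            "count_vm": [250] * 10 + [0] * 10,
        })
        perf = category_performance(table, cuts)
        assert perf[gc.SpeedCategory.SLOW][0] == 0.0

    def test_matches_direct_recount(self, rng):
        cuts = CutPointTable(placement="waist", axis="vm", epoch_length_s=15,
                             t1=140, t2=572, t3=990)
        import pandas as pd
        table = pd.DataFrame({
            "placement": "waist", "epoch_length_s": 15,
            "category": rng.integers(0, 4, size=500),
            "count_vm": rng.integers(0, 2000, size=500),
        })
        perf = category_performance(table, cuts)
        pred = [int(cuts.classify(c)) for c in table.count_vm]
        for cat in gc.SpeedCategory:
            c = int(cat)
            mine = [p == c for p, t in zip(pred, table.category) if t == c]
            others = [p != c for p, t in zip(pred, table.category) if t != c]
            assert perf[cat][0] == pytest.approx(np.mean(mine))
            assert perf[cat][1] == pytest.approx(np.mean(others))

    def test_stratum_mismatch_rejected(self):
        table, _ = _separable_table()
        cuts = CutPointTable(placement="ankle", axis="vm", epoch_length_s=15,
                             t1=401, t2=1862, t3=3265)
        with pytest.raises(ValueError, match="stratum"):
            category_performance(table, cuts)
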