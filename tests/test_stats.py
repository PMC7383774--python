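"""Agreement and diagnostic statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from rvtrack.stats import (
    bland_altman,
    group_compare,
    icc,
    operating_point,
    roc_auc,
    roc_curve_points,
    tertile_trend,
)


class TestBlandAltman:
    def test_identical_vectors(self):
        a = np.array([1.0, 2.0, 3.0])
        rep = bland_altman(a, a)
        assert rep.mean_diff == 0.0
        assert rep.loa_low == 0.0 and rep.loa_high == 0.0

    def test_hand_computed_two_pair_case(self):
        # diffs {1, -1}: mean 0, sample SD sqrt(2), LOA -/+ 1.96*sqrt(2)
        rep = bland_altman([2.0, 1.0], [1.0, 2.0])
        assert rep.mean_diff == 0.0
        assert rep.sd_diff == pytest.approx(math.sqrt(2), rel=1e-12)
        assert rep.loa_high == pytest.approx(1.96 * math.sqrt(2), rel=1e-12)
        assert rep.loa_low == pytest.approx(-1.96 * math.sqrt(2), rel=1e-12)

    def test_constant_bias(self):
        b = np.array([3.0, 5.0, 9.0, 11.0])
        rep = bland_altman(b + 5.0, b)
        assert rep.mean_diff == pytest.approx(5.0)
        assert rep.loa_low == pytest.approx(5.0)
        assert rep.loa_high == pytest.approx(5.0)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0) and rep.intercept == pytest.approx(5.0)

    def test_loa_cover_about_95_percent_of_gaussian_diffs(self):
        rng = np.random.default_rng(77)
        b = rng.normal(10, 2, 200)
        a = b + rng.normal(0.5, 1.0, 200)
        rep = bland_altman(a, b)
        inside = np.mean((a - b >= rep.loa_low) & (a - b <= rep.loa_high))
        assert 0.93 <= inside <= 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestICC:
    def test_identical_raters_varying_cases_is_exactly_one(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        res = icc(np.column_stack([col, col]))
        assert res.icc == 1.0

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        mat = rng.normal(0, 1, 12)[:, None] + rng.normal(0, 0.3, (12, 3))
        mine = icc(mat)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 3),
            "raters": np.tile(np.arange(3), 12),
            "ratings": mat.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="ratings")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0] if (ref.Type == "ICC(A,1)").any() \
            else ref[ref.Type == "ICC2"].iloc[0]
        assert mine.icc == pytest.approx(float(row["ICC"]), abs=1e-6)
        ci = np.asarray(row[ref.columns[-1]], dtype=float)
        assert mine.ci_low == pytest.approx(ci[0], abs=2e-2)
        assert mine.ci_high == pytest.approx(ci[1], abs=2e-2)

    def test_constant_offset_breaks_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        mat = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        mine = icc(mat)
        assert mine.icc < 1.0
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(3), 2),
            "raters": np.tile(np.arange(2), 3),
            "ratings": mat.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="ratings")
        sel = ref[ref.Type.isin(["ICC(A,1)", "ICC2"])].iloc[0]
        assert mine.icc == pytest.approx(float(sel["ICC"]), abs=1e-6)

    def test_pure_noise_has_low_icc(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        mat = np.column_stack([a, rng.permutation(a)])
        assert abs(icc(mat).icc) < 0.3

    def test_zero_between_case_variance_undefined(self):
        res = icc(np.ones((5, 2)))
        assert not res.defined and np.isnan(res.icc)

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            icc(np.ones((2, 2)))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [1.0, 1.5, 2.0, 3.0, 3.5, 4.0]
        labels = [1, 1, 1, 0, 0, 0]  # dysfunction scores lower
        auc, (lo, hi) = roc_auc(scores, labels)
        assert auc == 1.0
        assert lo <= auc <= hi <= 1.0

    def test_spec_four_point_examples(self):
        auc, _ = roc_auc([1, 2, 3, 4], [1, 1, 0, 0])
        assert auc == 1.0
        auc2, _ = roc_auc([1, 2, 3, 4], [1, 0, 1, 0])
        assert auc2 == 0.75

    def test_matches_bruteforce_pair_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 50))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            auc, _ = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([(p < q) + 0.5 * (p == q)
                             for p in pos for q in neg])
            assert auc == pytest.approx(brute, abs=1e-9)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_curve_spans_corners(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        pts = roc_curve_points(scores, labels)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)


class TestOperatingPoint:
    def test_perfect_separation_attains_both_one(self):
        scores = [0.5, 0.8, 1.1, 2.0, 2.5, 3.0]
        labels = [1, 1, 1, 0, 0, 0]
        rep = operating_point(scores, labels, sensitivity_floor=0.80)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.accuracy == 1.0 and rep.ppv == 1.0 and rep.npv == 1.0
        assert rep.sensitivity_floor_met

    def test_matches_exhaustive_enumeration(self):
        # 10 positives scoring below 10 negatives except one overlap
        pos = np.arange(1.0, 11.0)          # 1..10, dysfunction
        neg = np.arange(10.5, 20.5)         # 10.5..19.5
        neg[0] = 5.25                       # one negative dips into positives
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 10 + [0] * 10)

        risk = -scores
        uniq = np.unique(risk)
        cands = (uniq[:-1] + uniq[1:]) / 2
        best = None
        for cut in cands:
            pred = risk >= cut
            sens = (pred & (labels == 1)).sum() / 10
            spec = (~pred & (labels == 0)).sum() / 10
            if sens > 0.8:
                key = (spec, sens, -cut)
                if best is None or key > best:
                    best = key
        rep = operating_point(scores, labels, sensitivity_floor=0.80)
        assert rep.specificity == pytest.approx(best[0])
        assert rep.sensitivity == pytest.approx(best[1])

    def test_degenerate_floor_zero(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [1, 1, 0, 0]
        rep = operating_point(scores, labels, sensitivity_floor=0.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_unattainable_floor_flagged(self):
        # scores constant within each class but inverted: low sens everywhere
        scores = [3.0, 4.0, 1.0, 2.0]
        labels = [0, 0, 1, 1]
        rep = operating_point(scores, labels, sensitivity_floor=0.99,
                              lower_is_positive=False)
        assert not rep.sensitivity_floor_met


class TestGroupCompare:
    def test_hand_computed_pooled_t(self):
        t, p, (m0, s0), (m1, s1) = group_compare(
            [1, 2, 3, 7, 8, 9], [0, 0, 0, 1, 1, 1])
        assert t == pytest.approx(-7.3484692283495345, rel=1e-9)
        assert p == pytest.approx(0.0018262606682599833, rel=1e-6)
        assert (m0, m1) == (2.0, 8.0)

    def test_null_p_value_is_large(self):
        rng = np.random.default_rng(21)
        values = rng.normal(0, 1, 400)
        groups = np.repeat([0, 1], 200)
        _, p, _, _ = group_compare(values, groups)
        assert p > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [0, 0])


class TestTertileTrend:
    def test_monotone_construction_gives_increasing_means(self):
        rng = np.random.default_rng(5)
        strat = np.sort(rng.uniform(0, 10, 30))
        values = strat * 2.0 + rng.normal(0, 0.1, 30)
        means, p, assign = tertile_trend(values, strat)
        assert means[0] < means[1] < means[2]
        assert p < 1e-6
        assert sorted(np.bincount(assign)) == [10, 10, 10]

    def test_small_tertiles_rejected(self):
        with pytest.raises(ValueError):
            tertile_trend([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
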