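"""Confusion-derived metrics and the Student-t statistics layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lungmli import (
    ConfusionCounts,
    compare_methods,
    confusion,
    cross_test,
    f1_from_iou,
    iou,
    precision_recall_f1,
    stars_for_p,
    summarize,
    t_test,
)
from lungmli.metrics import (
    InsufficientDataError,
    NoDataError,
    ShapeError,
    UndefinedMetricError,
)

counts_strategy = st.tuples(
    st.integers(1, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500)
).map(lambda t: ConfusionCounts(*map(float, t)))


class TestConfusion:
    def test_perfect_match(self, rng):
        m = rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == m.sum()

    def test_complement(self, rng):
        m = rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
        c = confusion(1 - m, m)
        assert c.tp == 0 and c.tn == 0

    def test_handbuilt_pair_matches_pixel_enumeration(self, rng):
        pred = rng.integers(0, 2, size=(6, 6)).astype(np.uint8)
        truth = rng.integers(0, 2, size=(6, 6)).astype(np.uint8)
        c = confusion(pred, truth)
        tp = fp = fn = tn = 0
        for y in range(6):
            for x in range(6):
                if pred[y, x] and truth[y, x]:
                    tp += 1
                elif pred[y, x] and not truth[y, x]:
                    fp += 1
                elif not pred[y, x] and truth[y, x]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_fractions_sum_to_one(self, rng):
        pred = rng.integers(0, 2, size=(10, 10)).astype(np.uint8)
        truth = rng.integers(0, 2, size=(10, 10)).astype(np.uint8)
        f = confusion(pred, truth, normalize=True)
        assert f.total == pytest.approx(1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestIoU:
    def test_perfect(self):
        assert iou(ConfusionCounts(10, 0, 0, 10), "tissue") == 1.0

    def test_confusion_fraction_cells(self):
        # fractions TP=0.46, FP=0.02, FN=0.01 -> 0.46/0.49
        c = ConfusionCounts(tp=0.46, fp=0.02, fn=0.01, tn=0.51)
        assert iou(c, "tissue") == pytest.approx(0.46 / 0.49)
        assert iou(c, "tissue") == pytest.approx(0.9388, abs=5e-4)

    def test_zero_overlap(self):
        assert iou(ConfusionCounts(0, 5, 5, 10), "tissue") == 0.0

    def test_background_swaps_roles(self):
        c = ConfusionCounts(tp=3, fp=1, fn=2, tn=10)
        assert iou(c, "background") == pytest.approx(10 / 13)

    def test_empty_union_rejected(self):
        with pytest.raises(UndefinedMetricError):
            iou(ConfusionCounts(0, 0, 0, 5), "tissue")


class TestPrecisionRecallF1:
    def test_perfect(self):
        assert precision_recall_f1(ConfusionCounts(5, 0, 0, 5)) == (1.0, 1.0, 1.0)

    def test_half_precision_full_recall(self):
        # precision 0.5, recall 1.0 -> harmonic mean 2/3
        c = ConfusionCounts(tp=5, fp=5, fn=0, tn=5)
        p, r, f1 = precision_recall_f1(c)
        assert (p, r) == (0.5, 1.0)
        assert f1 == pytest.approx(2 / 3)

    @given(counts_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_f1_equals_iou_identity(self, c):
        # binary-class identity: F1 = 2*IoU / (1 + IoU), per class
        for k in ("tissue", "background"):
            _, _, f1 = precision_recall_f1(c, k)
            assert abs(f1 - f1_from_iou(iou(c, k))) < 1e-12

    @given(counts_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_iou_never_exceeds_f1(self, c):
        for k in ("tissue", "background"):
            assert iou(c, k) <= precision_recall_f1(c, k)[2] + 1e-15

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedMetricError):
            precision_recall_f1(ConfusionCounts(0, 0, 5, 5))


class TestF1FromIoU:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)])
    def test_closed_form(self, x, expected):
        assert f1_from_iou(x) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(UndefinedMetricError):
            f1_from_iou(1.5)


class TestSummarize:
    def test_single_perfect_pair(self, rng):
        m = rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
        s = summarize([(m, m)])
        assert s.iou_tissue == 1.0
        assert s.overall_f1 == 1.0

    def test_pooled_counts_match_concatenation(self, rng):
        m = rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
        pairs = [(m, m), (1 - m, m)]
        s = summarize(pairs)
        concat_pred = np.concatenate([m, 1 - m])
        concat_truth = np.concatenate([m, m])
        expected = iou(confusion(concat_pred, concat_truth), "tissue")
        assert s.iou_tissue == pytest.approx(expected)

    def test_overall_is_mean_of_classes(self, rng):
        pred = rng.integers(0, 2, size=(12, 12)).astype(np.uint8)
        truth = rng.integers(0, 2, size=(12, 12)).astype(np.uint8)
        s = summarize([(pred, truth)])
        assert s.overall_iou == pytest.approx((s.iou_tissue + s.iou_background) / 2)
        assert s.overall_f1 == pytest.approx((s.f1_tissue + s.f1_background) / 2)

    def test_empty_rejected(self):
        with pytest.raises(NoDataError):
            summarize([])


class TestTTest:
    def test_identical_groups(self):
        cmp = t_test([1, 2, 3], [1, 2, 3])
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == pytest.approx(1.0)
        assert cmp.stars == "ns"

    def test_hand_example(self):
        # pooled sd 1, se = sqrt(2/3), t = -3/se
        cmp = t_test([1, 2, 3], [4, 5, 6])
        assert cmp.t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert cmp.degrees_of_freedom == 4
        assert cmp.p_value == pytest.approx(0.0213, abs=1e-3)
        assert cmp.stars == "*"

    def test_swap_symmetry(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 9)
        ab = t_test(a, b)
        ba = t_test(b, a)
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_matches_reference_on_random_instances(self, rng):
        # 100 random instances against scipy's independent implementation
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(2, 20))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(2, 20))
            got = t_test(a, b)
            t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
            assert got.t_statistic == pytest.approx(t_ref, abs=1e-10)
            assert got.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_welch_matches_reference(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 3, 7)
        got = t_test(a, b, equal_variance=False)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert got.t_statistic == pytest.approx(t_ref, abs=1e-10)
        assert got.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_one_sided_halves_p(self):
        two = t_test([1, 2, 3], [4, 5, 6], sides="two")
        one = t_test([1, 2, 3], [4, 5, 6], sides="one")
        assert one.p_value == pytest.approx(two.p_value / 2)

    def test_zero_variance_equal_means(self):
        cmp = t_test([2.0, 2.0], [2.0, 2.0])
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_too_small_group(self):
        with pytest.raises(InsufficientDataError):
            t_test([1.0], [1.0, 2.0])

    def test_star_thresholds(self):
        assert stars_for_p(0.04) == "*"
        assert stars_for_p(0.009) == "**"
        assert stars_for_p(0.0009) == "***"
        assert stars_for_p(0.2) == "ns"


class TestCrossTest:
    def test_three_mice_three_pairs(self, rng):
        values = {f"m{i}": list(rng.normal(50, 5, 12)) for i in range(3)}
        table = cross_test(values)
        assert len(table) == 3
        assert set(zip(table["mouse_a"], table["mouse_b"])) == {
            ("m0", "m1"), ("m0", "m2"), ("m1", "m2"),
        }

    def test_identical_mice_all_p_one(self):
        vals = [1.0, 2.0, 3.0]
        table = cross_test({"a": vals, "b": vals, "c": vals})
        assert (table["p_value"] == 1.0).all()

    def test_matches_pairwise_t_test(self, rng):
        values = {f"m{i}": list(rng.normal(50, 5, 10)) for i in range(3)}
        table = cross_test(values)
        for row in table.itertuples():
            ref = t_test(values[row.mouse_a], values[row.mouse_b])
            assert row.p_value == pytest.approx(ref.p_value)

    def test_single_mouse_rejected(self):
        with pytest.raises(InsufficientDataError):
            cross_test({"a": [1.0, 2.0]})


class TestCompareMethods:
    @staticmethod
    def _frame(rng, scale=1.0):
        rows = []
        for method in ("manual", "classical", "dl"):
            for group, mu in (("control", 40), ("smoker", 60)):
                for v in rng.normal(mu, 5, 12):
                    rows.append({"method": method, "group": group, "Lm": v * scale})
        return pd.DataFrame(rows)

    def test_identical_inputs_identical_comparisons(self):
        rng = np.random.default_rng(0)
        df = self._frame(rng)
        base = df[df["method"] == "manual"].copy()
        clones = pd.concat(
            [base.assign(method=m) for m in ("manual", "classical", "dl")],
            ignore_index=True,
        )
        comparisons, table = compare_methods(clones)
        ps = table["p_value"].unique()
        assert len(ps) == 1

    def test_scaling_leaves_p_unchanged(self):
        df = self._frame(np.random.default_rng(1))
        _, t1 = compare_methods(df)
        scaled = df.copy()
        scaled.loc[scaled["method"] == "dl", "Lm"] *= 1.33
        _, t2 = compare_methods(scaled)
        p1 = t1.set_index("method").loc["dl", "p_value"]
        p2 = t2.set_index("method").loc["dl", "p_value"]
        assert p1 == pytest.approx(p2)

    def test_missing_group_rejected(self):
        df = pd.DataFrame({"method": ["m"], "group": ["control"], "Lm": [1.0]})
        with pytest.raises(NoDataError):
            compare_methods(df)
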