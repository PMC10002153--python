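"""Segmentation IoU and the agreement-statistics battery.

The statistical functions are checked against independent oracles written
from the closed forms: the t and chi-square tail probabilities come from
numerical integration of the density / the complementary error function,
the exact McNemar p from binomial coefficients.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from molarmetrics.errors import (
    ConstantSeriesError,
    LabelError,
    ShapeMismatchError,
)
from molarmetrics.evalstats import (
    FN,
    FP,
    TP,
    compare,
    decision_agreement,
    mae_sd,
    mcnemar_test,
    paired_t_test,
    pearson_r,
    render_confusion_map,
    segmentation_eval,
)

# ---------------------------------------------------------------------------
# independent oracles


def t_two_sided_p(t_stat: float, df: int) -> float:
    """Two-sided Student-t tail by numerical integration of the density."""

    def pdf(x):
        return (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    tail, _ = quad(pdf, abs(t_stat), math.inf)
    return min(1.0, 2 * tail)


def exact_binomial_two_sided_p(k_small: int, n: int) -> float:
    """Two-sided sign-test p for the smaller discordant count."""
    tail = sum(math.comb(n, i) for i in range(k_small + 1)) / 2**n
    return min(1.0, 2 * tail)


def chi2_1df_p(stat: float) -> float:
    return math.erfc(math.sqrt(stat / 2))


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentationEval:
    def test_identical_masks_give_unit_iou(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        ev = segmentation_eval(mask, mask)
        assert ev.iou == 1.0 and ev.fp == 0 and ev.fn == 0

    def test_disjoint_masks_give_zero_iou(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert segmentation_eval(a, b).iou == 0.0

    def test_shifted_squares_worked_example(self):
        truth = np.zeros((4, 4), dtype=bool)
        pred = np.zeros((4, 4), dtype=bool)
        truth[0:2, 0:2] = True
        pred[1:3, 1:3] = True
        ev = segmentation_eval(truth, pred)
        assert (ev.tp, ev.fp, ev.fn) == (1, 3, 3)
        assert ev.iou == pytest.approx(1 / 7)
        assert (ev.confusion_map == TP).sum() == 1
        assert (ev.confusion_map == FP).sum() == 3
        assert (ev.confusion_map == FN).sum() == 3

    def test_iou_is_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = rng.random((16, 16)) < 0.4
            i = rng.random((16, 16)) < 0.4
            assert segmentation_eval(g, i).iou == segmentation_eval(i, g).iou

    def test_both_empty_flagged(self):
        empty = np.zeros((4, 4), dtype=bool)
        ev = segmentation_eval(empty, empty)
        assert ev.iou == 1.0 and ev.both_empty

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            segmentation_eval(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_confusion_map_colors(self):
        truth = np.zeros((2, 2), dtype=bool)
        pred = np.zeros((2, 2), dtype=bool)
        truth[0, 0] = pred[0, 0] = True  # TP
        pred[0, 1] = True  # FP
        truth[1, 0] = True  # FN
        rgb = render_confusion_map(segmentation_eval(truth, pred).confusion_map)
        assert tuple(rgb[0, 0]) == (0, 160, 60)
        assert tuple(rgb[0, 1]) == (255, 150, 0)
        assert tuple(rgb[1, 0]) == (210, 30, 30)
        assert tuple(rgb[1, 1]) == (0, 0, 0)


# ---------------------------------------------------------------------------
# statistics


class TestMaeSd:
    def test_identical_series(self):
        assert mae_sd([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_two_point_mean(self):
        mae, _ = mae_sd([0.02, 0.06], [0.0, 0.0])
        assert mae == pytest.approx(0.04)

    def test_closed_form_sample_sd(self):
        mae, sd = mae_sd([1, 2, 3, 4], [0, 0, 0, 0])
        assert mae == pytest.approx(2.5)
        assert sd == pytest.approx(math.sqrt(5 / 3), abs=1e-9)  # 1.2910


class TestPearson:
    def test_perfect_linear_dependence(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_three_point_example(self):
        r, _ = pearson_r([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSeriesError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_p_matches_integration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, p = pearson_r(x, y)
            t = r * math.sqrt((n - 2) / (1 - r * r))
            assert p == pytest.approx(t_two_sided_p(t, n - 2), abs=1e-6)


class TestPairedT:
    def test_zero_mean_difference(self):
        t, p = paired_t_test([1, 0, 1, 0], [0, 1, 0, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        # d = (1, 2, 3): t = 2*sqrt(3), p from the t-distribution tail
        t, p = paired_t_test([1, 2, 3], [0, 0, 0])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-9)
        assert p == pytest.approx(t_two_sided_p(2 * math.sqrt(3), 2), abs=1e-6)
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_identical_series_rejected(self):
        with pytest.raises(ConstantSeriesError):
            paired_t_test([1, 2, 3], [1, 2, 3])


class TestMcNemar:
    @staticmethod
    def _labels(n00, n01, n10, n11):
        a = ["m"] * n00 + ["m"] * n01 + ["a"] * n10 + ["a"] * n11
        b = ["m"] * n00 + ["a"] * n01 + ["m"] * n10 + ["a"] * n11
        return a, b

    def test_symmetric_discordance_exact_p_is_one(self):
        a, b = self._labels(10, 5, 5, 10)
        _, p = mcnemar_test(a, b)
        assert p == pytest.approx(1.0)

    def test_chi_square_path_above_threshold(self):
        a, b = self._labels(10, 20, 10, 10)
        stat, p = mcnemar_test(a, b)
        assert stat == pytest.approx(100 / 30, abs=1e-9)
        assert p == pytest.approx(chi2_1df_p(100 / 30), abs=1e-6)

    def test_exact_path_matches_binomial_oracle(self):
        a, b = self._labels(8, 7, 2, 8)
        _, p = mcnemar_test(a, b)
        assert p == pytest.approx(exact_binomial_two_sided_p(2, 9), abs=1e-9)

    def test_full_agreement(self):
        a = ["m", "a", "m", "a"]
        _, p = mcnemar_test(a, list(a))
        assert p == pytest.approx(1.0)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(LabelError):
            mcnemar_test(["x", "y", "z"], ["x", "y", "z"])


class TestAgreementAndReport:
    def test_agreement_fractions(self):
        assert decision_agreement(["m", "a"], ["m", "a"]) == 1.0
        assert decision_agreement(["m", "a"], ["a", "m"]) == 0.0
        agree = decision_agreement(["m"] * 54 + ["a"] * 3, ["m"] * 57)
        assert agree == pytest.approx(54 / 57, abs=1e-9)
        assert round(agree, 4) == 0.9474

    def test_compare_bundles_full_battery(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.02, 0.3, 40)
        y = x + rng.normal(0, 0.02, 40)
        dx = np.where(x < 0.08, "adult", "minor")
        dy = np.where(y < 0.08, "adult", "minor")
        rep = compare(x, y, dx, dy)
        assert rep.n == 40
        assert 0 <= rep.agreement_fraction <= 1
        assert -1 <= rep.pearson_r <= 1
        assert rep.mae == pytest.approx(np.abs(x - y).mean())
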