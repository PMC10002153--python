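"""Segmentation evaluation and the statistical comparison battery.

Segmentation quality is scored with the intersection-over-union metric
IoU = TP / (TP + FN + FP) per region (coronal, apical, overall = union of
the two), with a per-pixel confusion map for error visualization (green
true positives, orange false positives, red false negatives).

Method-versus-expert comparisons use: mean absolute error ± sample SD,
Pearson correlation, a paired two-sided t-test, McNemar's test on the
minor/adult decisions (exact binomial when fewer than 25 discordant pairs,
otherwise the chi-square statistic without continuity correction), and the
raw decision-agreement fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import ConstantSeriesError, LabelError, ShapeMismatchError

# confusion map label codes
TN, TP, FP, FN = 0, 1, 2, 3

#: Fig.-2-style colors for confusion overlays
CONFUSION_COLORS = {
    TN: (0, 0, 0),
    TP: (0, 160, 60),  # green
    FP: (255, 150, 0),  # orange
    FN: (210, 30, 30),  # red
}


@dataclass
class SegmentationEval:
    """Pixel-wise confusion counts and IoU for one region of one image."""

    tp: int
    fp: int
    fn: int
    iou: float
    region: str
    confusion_map: np.ndarray
    both_empty: bool = False


@dataclass
class ComparisonReport:
    """The full statistical battery for one method-vs-reference comparison."""

    mae: float
    sd_ae: float
    pearson_r: float
    pearson_p: float
    t_stat: float
    t_p: float
    mcnemar_stat: float
    mcnemar_p: float
    agreement_fraction: float
    n: int


def segmentation_eval(
    truth: np.ndarray, inferred: np.ndarray, region: str = "overall"
) -> SegmentationEval:
    """Confusion counts, IoU, and per-pixel confusion map for one mask pair."""
    truth = np.asarray(truth, dtype=bool)
    inferred = np.asarray(inferred, dtype=bool)
    if truth.shape != inferred.shape:
        raise ShapeMismatchError("masks must share a shape")
    tp = int(np.count_nonzero(truth & inferred))
    fp = int(np.count_nonzero(~truth & inferred))
    fn = int(np.count_nonzero(truth & ~inferred))
    confusion = np.full(truth.shape, TN, dtype=np.uint8)
    confusion[truth & inferred] = TP
    confusion[~truth & inferred] = FP
    confusion[truth & ~inferred] = FN
    denom = tp + fp + fn
    both_empty = denom == 0
    iou = 1.0 if both_empty else tp / denom
    return SegmentationEval(
        tp=tp, fp=fp, fn=fn, iou=iou, region=region,
        confusion_map=confusion, both_empty=both_empty,
    )


def render_confusion_map(confusion: np.ndarray) -> np.ndarray:
    """RGB uint8 rendering of a confusion map (green TP, orange FP, red FN)."""
    rgb = np.zeros(confusion.shape + (3,), dtype=np.uint8)
    for code, color in CONFUSION_COLORS.items():
        rgb[confusion == code] = color
    return rgb


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeMismatchError("series must have equal length")
    return x, y


def mae_sd(x, y) -> tuple[float, float]:
    """Mean and sample SD (n−1 denominator) of the absolute errors |x−y|."""
    x, y = _paired(x, y)
    if x.size < 2:
        raise ShapeMismatchError("need at least 2 paired values")
    err = np.abs(x - y)
    return float(err.mean()), float(err.std(ddof=1))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p (t transform, n−2 df)."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ShapeMismatchError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ConstantSeriesError("zero variance series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(x, y) -> tuple[float, float]:
    """Student's paired two-sided t-test on d = x − y (df = n−1)."""
    x, y = _paired(x, y)
    if x.size < 2:
        raise ShapeMismatchError("need at least 2 paired values")
    d = x - y
    if np.all(d == d[0]) and d[0] == 0:
        raise ConstantSeriesError("identical series: t is undefined")
    if d.std(ddof=1) == 0:
        raise ConstantSeriesError("zero-variance differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    uniq = set(np.unique(arr).tolist())
    if len(uniq) > 2:
        raise LabelError(f"decisions must be binary, got labels {sorted(map(str, uniq))}")
    return arr


def mcnemar_test(
    decisions_a, decisions_b, exact_threshold: int = 25
) -> tuple[float, float]:
    """McNemar's test on paired binary decisions.

    With fewer than ``exact_threshold`` discordant pairs the exact two-sided
    binomial p is used and the statistic reported is the smaller discordant
    count; otherwise the chi-square statistic (n01−n10)²/(n01+n10) with 1 df
    and no continuity correction.
    """
    a = _as_binary(decisions_a)
    b = _as_binary(decisions_b)
    if a.shape != b.shape:
        raise ShapeMismatchError("decision series must have equal length")
    labels = sorted(set(np.unique(a).tolist()) | set(np.unique(b).tolist()))
    if len(labels) > 2:
        raise LabelError("decision series use more than two labels")
    if len(labels) == 1:
        return 0.0, 1.0  # full agreement, no discordant pairs
    pos = labels[1]
    a_pos = a == pos
    b_pos = b == pos
    n01 = int(np.count_nonzero(~a_pos & b_pos))
    n10 = int(np.count_nonzero(a_pos & ~b_pos))
    table = np.array(
        [
            [int(np.count_nonzero(~a_pos & ~b_pos)), n01],
            [n10, int(np.count_nonzero(a_pos & b_pos))],
        ]
    )
    if n01 + n10 == 0:
        return 0.0, 1.0
    exact = (n01 + n10) < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def decision_agreement(decisions_a, decisions_b) -> float:
    """Proportion of identical paired decisions."""
    a = np.asarray(decisions_a)
    b = np.asarray(decisions_b)
    if a.shape != b.shape or a.size == 0:
        raise ShapeMismatchError("decision series must have equal nonzero length")
    return float(np.count_nonzero(a == b) / a.size)


def compare(
    scores_x, scores_y, decisions_x=None, decisions_y=None
) -> ComparisonReport:
    """Run the full battery on paired scores (and optionally decisions)."""
    x, y = _paired(scores_x, scores_y)
    mae, sd = mae_sd(x, y)
    r, rp = pearson_r(x, y)
    t, tp_ = paired_t_test(x, y)
    if decisions_x is not None and decisions_y is not None:
        stat, mp = mcnemar_test(decisions_x, decisions_y)
        agree = decision_agreement(decisions_x, decisions_y)
    else:
        stat, mp, agree = float("nan"), float("nan"), float("nan")
    return ComparisonReport(
        mae=mae, sd_ae=sd, pearson_r=r, pearson_p=rp,
        t_stat=t, t_p=tp_, mcnemar_stat=stat, mcnemar_p=mp,
        agreement_fraction=agree, n=int(x.size),
    )
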