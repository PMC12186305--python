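"""Segmentation evaluation and the group-comparison statistics layer.

Pixelwise confusion counts with tissue as the positive class, the derived
per-class IoU / precision / recall / F1 (for the binary case IoU_k =
TP_k / (TP_k + FN_k + FP_k), and F1 is the harmonic mean of precision and
recall, equivalently F1 = 2*IoU/(1+IoU)), pooled summaries over a dataset
split, and the study's statistics: equal-variance two-sample Student
t-tests between groups, pairwise within-group cross-tests for homogeneity,
and the three-way method comparison (manual / classical / DL) of group mean
Lm values with significance stars (* p<=0.05, ** p<=0.01, *** p<=0.001).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "GroupComparison",
    "confusion",
    "iou",
    "precision_recall_f1",
    "f1_from_iou",
    "summarize",
    "t_test",
    "cross_test",
    "compare_methods",
    "stars_for_p",
]


class ShapeError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class NoDataError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts (or fractions) with tissue as the positive class."""

    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    def as_fractions(self) -> "ConfusionCounts":
        t = self.total
        if t == 0:
            raise UndefinedMetricError("empty confusion counts")
        return ConfusionCounts(self.tp / t, self.fp / t, self.fn / t, self.tn / t)

    def swapped(self) -> "ConfusionCounts":
        """Counts with the background class treated as positive."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)

    def to_frame(self) -> pd.DataFrame:
        """Prediction-by-annotation table with marginal totals."""
        f = self
        data = {
            "tissue": [f.tp, f.fn, f.tp + f.fn],
            "background": [f.fp, f.tn, f.fp + f.tn],
        }
        frame = pd.DataFrame(data, index=["pred_tissue", "pred_background", "total"])
        frame["total"] = frame.sum(axis=1)
        return frame


@dataclass(frozen=True)
class SegMetrics:
    iou_tissue: float
    iou_background: float
    overall_iou: float
    precision_tissue: float
    recall_tissue: float
    f1_tissue: float
    precision_background: float
    recall_background: float
    f1_background: float
    overall_f1: float


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str


def stars_for_p(p: float) -> str:
    """Significance stars: * p<=0.05, ** p<=0.01, *** p<=0.001, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Confusion counts and derived metrics
# ---------------------------------------------------------------------------


def confusion(pred: np.ndarray, truth: np.ndarray, normalize: bool = False) -> ConfusionCounts:
    """Pixelwise confusion counts between a predicted and a reference mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    counts = ConfusionCounts(
        tp=float(np.sum(p & t)),
        fp=float(np.sum(p & ~t)),
        fn=float(np.sum(~p & t)),
        tn=float(np.sum(~p & ~t)),
    )
    return counts.as_fractions() if normalize else counts


def _class_counts(counts: ConfusionCounts, class_k: str) -> ConfusionCounts:
    if class_k == "tissue":
        return counts
    if class_k == "background":
        return counts.swapped()
    raise UndefinedMetricError(f"unknown class {class_k!r}")


def iou(counts: ConfusionCounts, class_k: str = "tissue") -> float:
    """Intersection over union for one class: TP / (TP + FN + FP)."""
    c = _class_counts(counts, class_k)
    denom = c.tp + c.fn + c.fp
    if denom == 0:
        raise UndefinedMetricError(f"empty union for class {class_k!r}")
    return c.tp / denom


def precision_recall_f1(counts: ConfusionCounts, class_k: str = "tissue") -> tuple[float, float, float]:
    """Per-class precision, recall and their harmonic mean F1."""
    c = _class_counts(counts, class_k)
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        raise UndefinedMetricError(f"zero denominator for class {class_k!r}")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        return precision, recall, 0.0
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def f1_from_iou(iou_value: float) -> float:
    """Binary-class identity F1 = 2*IoU / (1 + IoU)."""
    if not 0.0 <= iou_value <= 1.0:
        raise UndefinedMetricError(f"IoU {iou_value} outside [0, 1]")
    return 2.0 * iou_value / (1.0 + iou_value)


def _prf_pooled(counts: ConfusionCounts, class_k: str) -> tuple[float, float, float]:
    # zero-division -> 0 convention, so a never-predicted class scores 0
    # instead of aborting a whole-split summary
    c = _class_counts(counts, class_k)
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def summarize(pairs) -> SegMetrics:
    """Pooled per-class metrics over (pred, truth) mask pairs.

    Confusion counts are pooled over all pixels of every pair, per-class
    metrics are computed from the pooled counts, and "overall" values are
    the unweighted mean of the tissue and background values.  A class that
    is never predicted scores 0 rather than raising.
    """
    pairs = list(pairs)
    if not pairs:
        raise NoDataError("summarize needs at least one (pred, truth) pair")
    tp = fp = fn = tn = 0.0
    for pred, truth in pairs:
        c = confusion(pred, truth)
        tp, fp, fn, tn = tp + c.tp, fp + c.fp, fn + c.fn, tn + c.tn
    counts = ConfusionCounts(tp, fp, fn, tn)
    iou_t = iou(counts, "tissue")
    iou_b = iou(counts, "background")
    p_t, r_t, f_t = _prf_pooled(counts, "tissue")
    p_b, r_b, f_b = _prf_pooled(counts, "background")
    return SegMetrics(
        iou_tissue=iou_t,
        iou_background=iou_b,
        overall_iou=(iou_t + iou_b) / 2,
        precision_tissue=p_t,
        recall_tissue=r_t,
        f1_tissue=f_t,
        precision_background=p_b,
        recall_background=r_b,
        f1_background=f_b,
        overall_f1=(f_t + f_b) / 2,
    )


# ---------------------------------------------------------------------------
# Student t statistics
# ---------------------------------------------------------------------------


def t_test(
    values_a,
    values_b,
    equal_variance: bool = True,
    sides: str = "two",
) -> GroupComparison:
    """Two-sample Student t-test between value lists.

    By default the pooled-variance (equal-variance) form: t is the
    difference of means divided by the standard error of the difference,
    with n_a + n_b - 2 degrees of freedom.  ``sides`` is "two" or "one"
    (one-sided: H1 is mean_a < mean_b when t < 0, mean_a > mean_b
    otherwise, i.e. p = P(|T| > |t|)/2).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least two values")
    if sides not in ("one", "two"):
        raise InsufficientDataError("sides must be 'one' or 'two'")
    na, nb = a.size, b.size
    ma, mb = float(a.mean()), float(b.mean())
    sa, sb = float(a.std(ddof=1)), float(b.std(ddof=1))
    if equal_variance:
        df = na + nb - 2
        sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        va, vb = sa**2 / na, sb**2 / nb
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1)) if se > 0 else na + nb - 2
    if se == 0:
        t = 0.0 if ma == mb else np.inf * np.sign(ma - mb)
        p = 1.0 if ma == mb else 0.0
    else:
        t = (ma - mb) / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
        p = min(p, 1.0)
    if sides == "one":
        p = p / 2.0
    return GroupComparison(
        mean_a=ma,
        mean_b=mb,
        sd_a=sa,
        sd_b=sb,
        n_a=int(na),
        n_b=int(nb),
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=float(p),
        stars=stars_for_p(float(p)),
    )


def cross_test(group_values: dict[str, list[float]], **t_kwargs) -> pd.DataFrame:
    """Pairwise homogeneity tests between the mice of one group.

    Every unordered pair of mice is compared with :func:`t_test` on their
    image-level Lm lists.  Non-significance indicates homogeneity (the null
    hypothesis is that the two mice share the same mean MLI).
    """
    mice = list(group_values)
    if len(mice) < 2:
        raise InsufficientDataError("cross test needs at least two mice")
    rows = []
    for a, b in itertools.combinations(mice, 2):
        cmp = t_test(group_values[a], group_values[b], **t_kwargs)
        rows.append(
            {
                "mouse_a": a,
                "mouse_b": b,
                "t": cmp.t_statistic,
                "df": cmp.degrees_of_freedom,
                "p_value": cmp.p_value,
                "stars": cmp.stars,
                "significant": cmp.p_value <= 0.05,
            }
        )
    return pd.DataFrame(rows)


def compare_methods(results: pd.DataFrame, **t_kwargs) -> tuple[dict[str, GroupComparison], pd.DataFrame]:
    """Control-vs-smoker comparison for each measurement method.

    ``results`` is tidy with columns ``method``, ``group`` and ``Lm`` (one
    row per image and method).  Returns per-method comparisons (control as
    group a, smoker as group b) and a summary table of group means, standard
    deviations, p-values and stars.
    """
    required = {"method", "group", "Lm"}
    if not required.issubset(results.columns):
        raise NoDataError(f"results must have columns {sorted(required)}")
    comparisons: dict[str, GroupComparison] = {}
    rows = []
    for method, sub in results.groupby("method"):
        groups = sorted(sub["group"].unique())
        if len(groups) != 2:
            raise NoDataError(f"method {method!r} must supply exactly two groups")
        a = sub.loc[sub["group"] == groups[0], "Lm"].to_numpy()
        b = sub.loc[sub["group"] == groups[1], "Lm"].to_numpy()
        cmp = t_test(a, b, **t_kwargs)
        comparisons[str(method)] = cmp
        rows.append(
            {
                "method": method,
                "group_a": groups[0],
                "group_b": groups[1],
                "mean_a": cmp.mean_a,
                "mean_b": cmp.mean_b,
                "sd_a": cmp.sd_a,
                "sd_b": cmp.sd_b,
                "t": cmp.t_statistic,
                "p_value": cmp.p_value,
                "stars": cmp.stars,
            }
        )
    return comparisons, pd.DataFrame(rows)
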