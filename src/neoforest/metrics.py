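"""Classifier evaluation for rare-positive screening data.

Besides the usual ROC/PR machinery this module implements the partial
AUC restricted to false-positive rates below 0.1 ("AUC01"), the paired
DeLong test for comparing correlated ROC curves, the
sensitivity/specificity-intersection operating point used to binarise
continuous scores, and per-patient top-k capture of true positives.

AUC01 is reported *unnormalised*: it is the raw area over
fpr in [0, 0.1], so a perfect classifier scores 0.1 and chance scores
0.005.  A McClish-normalised variant is available behind a flag.

Score orientation is explicit throughout because one widely used
baseline -- the eluted-ligand percentile rank -- is better when LOW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc01: float


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_curve(scores, labels) -> ROCResult:
    """ROC by threshold sweep (ties grouped), AUC by trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr, tpr, thr, auc, partial_auc_from_points(fpr, tpr))


def partial_auc_from_points(
    fpr, tpr, fpr_max: float = 0.1, normalized: bool = False
) -> float:
    """Area under the ROC polyline restricted to fpr in [0, fpr_max].

    The curve is linearly interpolated at fpr_max.  Unnormalised range
    is [0, fpr_max]; with ``normalized`` the McClish transform maps it
    to [0.5, 1] relative to the chance diagonal.
    """
    if not 0 < fpr_max <= 1:
        raise ValueError("fpr_max must lie in (0, 1]")
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    # walk the polyline segment by segment so vertical jumps (tied
    # scores) are preserved and the cut at fpr_max interpolates linearly
    area = 0.0
    for (x0, y0), (x1, y1) in zip(zip(fpr, tpr), zip(fpr[1:], tpr[1:])):
        if x0 >= fpr_max:
            break
        if x1 <= fpr_max:
            area += (x1 - x0) * (y0 + y1) / 2.0
        else:
            y_cut = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            area += (fpr_max - x0) * (y0 + y_cut) / 2.0
    area = float(area)
    if not normalized:
        return area
    min_area = 0.5 * fpr_max**2
    max_area = fpr_max
    return 0.5 * (1.0 + (area - min_area) / (max_area - min_area))


def partial_auc(scores, labels, fpr_max: float = 0.1, normalized: bool = False) -> float:
    roc = roc_curve(scores, labels)
    return partial_auc_from_points(roc.fpr, roc.tpr, fpr_max, normalized)


def auc(scores, labels) -> float:
    return roc_curve(scores, labels).auc


def pr_metrics(scores, labels):
    """Precision-recall points and interpolation-free average precision."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    precision, recall, thr = _skm.precision_recall_curve(labels, scores)
    ap = float(_skm.average_precision_score(labels, scores))
    return precision, recall, thr, ap


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc_val = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m    # over negatives
    return auc_val, v01, v10


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong comparison of two AUCs on the same labelled set.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value.
    Identical score vectors give p = 1 by convention; zero estimated
    variance with a non-zero AUC difference is an error.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores must share the label vector's shape")

    auc_a, v01_a, v10_a = _delong_structural(scores_a, labels)
    auc_b, v01_b, v10_b = _delong_structural(scores_b, labels)
    m, n = len(v01_a), len(v10_a)
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    cov = s01 / m + s10 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if np.allclose(scores_a, scores_b):
        return float(auc_a), float(auc_b), 0.0, 1.0
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return float(auc_a), float(auc_b), 0.0, 1.0
        raise ValueError("zero variance estimate with unequal AUCs")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), float(z), p


# ---------------------------------------------------------------------------
# Operating point and confusion-matrix statistics


def _orient(scores, higher_is_positive: bool) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    return scores if higher_is_positive else -scores


def sens_spec_intersection(
    scores, labels, higher_is_positive: bool = True
) -> float:
    """Score cutoff where sensitivity and specificity curves cross.

    Candidates are the observed score values plus midpoints between
    consecutive distinct values; the candidate minimising
    |sensitivity - specificity| wins, ties broken toward higher
    specificity.  With constant scores the single candidate is returned.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    s = _orient(scores, higher_is_positive)
    uniq = np.unique(s)
    candidates = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0])
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_thr, best_gap, best_spec = None, np.inf, -1.0
    for thr in np.sort(candidates):
        pred = s >= thr
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12 or (
            abs(gap - best_gap) <= 1e-12 and spec > best_spec
        ):
            best_thr, best_gap, best_spec = thr, gap, spec
    return float(best_thr if higher_is_positive else -best_thr)


def confusion_at(
    scores, labels, threshold: float, higher_is_positive: bool = True
) -> ConfusionMatrix:
    """Counts at a cutoff; a score equal to the threshold counts positive."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = np.asarray(labels)
    s = _orient(scores, higher_is_positive)
    thr = threshold if higher_is_positive else -threshold
    pred = s >= thr
    pos = labels == 1
    return ConfusionMatrix(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = (float(x) for x in (cm.tp, cm.fp, cm.fn, cm.tn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def per_patient_topk(
    scores,
    labels,
    patient_ids,
    k: int,
    peptide_ids=None,
    higher_is_better: bool = True,
):
    """Fraction of each patient's true positives captured in its top k.

    Patients without any positive peptide map to None (capture is
    undefined).  Ties at rank k are broken by peptide id so the ranking
    is reproducible across runs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = _orient(scores, higher_is_better)
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    if peptide_ids is None:
        peptide_ids = np.arange(len(labels))
    peptide_ids = np.asarray(peptide_ids)

    result: dict = {}
    for patient in np.unique(patient_ids):
        mask = patient_ids == patient
        lab = labels[mask]
        if lab.sum() == 0:
            result[str(patient)] = None
            continue
        order = np.lexsort((peptide_ids[mask], -scores[mask]))
        captured = lab[order[:k]].sum()
        result[str(patient)] = float(captured / lab.sum())
    return result
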