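"""ROC statistics, DeLong AUC comparison and cross-validation plans.

AUC is computed in the Mann-Whitney (midrank) formulation, which equals
the trapezoidal area under the empirical ROC curve. Paired AUCs are
compared with the fast structural-components DeLong algorithm; the same
components give the single-model standard error used for 95% CIs.

Cross-validation follows a five-fold 3:1:1 design: patients are
stratified by label into five folds; rotation ``r`` uses fold ``r`` as
test, fold ``r+1`` as validation and the remaining three folds as
training, so every patient is tested exactly once across the five
rotations. Both views of a patient always share a fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CVPlan",
    "ROCResult",
    "DeLongResult",
    "auc",
    "delong_test",
    "delong_ci",
    "make_cv_plan",
    "operating_point",
    "youden_threshold",
    "patient_level_scores",
    "roc_result",
]


# ---------------------------------------------------------------------------
# AUC and DeLong
# ---------------------------------------------------------------------------

def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute an AUC")
    return scores, labels


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Ties are handled with midranks, equivalent to the trapezoidal area
    under the empirical ROC curve.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = scores[labels == 1]
    m, n = pos.size, scores.size - pos.size
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def _structural_components(scores, labels):
    """DeLong V10 (per positive) and V01 (per negative) components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    rank_all = stats.rankdata(np.concatenate([pos, neg]))
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    a = float((rank_all[:m].sum() - m * (m + 1) / 2) / (m * n))
    return a, v10, v01


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    var_diff: float
    covariance: np.ndarray  # 2x2 covariance of (auc_a, auc_b)
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test for paired correlated AUCs.

    Both score vectors must refer to the same cases in the same order.
    If the variance of the AUC difference is (numerically) zero -- e.g.
    both models are identical or both separate the classes perfectly --
    the comparison is degenerate and reported as ``z = 0, p = 1`` with
    ``degenerate=True``.
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, labels_b = _check_scores_labels(scores_b, labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    a1, v10_1, v01_1 = _structural_components(scores_a, labels)
    a2, v10_2, v01_2 = _structural_components(scores_b, labels)
    m, n = v10_1.size, v01_1.size
    if m < 2 or n < 2:  # component covariance needs >=2 per class
        return DeLongResult(a1, a2, 0.0, 1.0, 0.0, np.zeros((2, 2)), True)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var_diff <= np.finfo(float).eps:
        return DeLongResult(a1, a2, 0.0, 1.0, max(var_diff, 0.0), cov, True)
    z = (a1 - a2) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(a1, a2, float(z), float(p), var_diff, cov, False)


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with a DeLong normal-approximation CI, truncated to [0, 1].

    Returns ``(auc, lo, hi)``.
    """
    scores, labels = _check_scores_labels(scores, labels)
    a, v10, v01 = _structural_components(scores, labels)
    var = 0.0
    if v10.size > 1:
        var += float(np.var(v10, ddof=1)) / v10.size
    if v01.size > 1:
        var += float(np.var(v01, ddof=1)) / v01.size
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return a, float(max(0.0, a - half)), float(min(1.0, a + half))


# ---------------------------------------------------------------------------
# Operating points
# ---------------------------------------------------------------------------

def youden_threshold(scores, labels) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct scores plus
    sentinels below/above the observed range; a score is called
    positive when it is >= the threshold. Ties in J are broken towards
    the larger threshold (the more specific operating point), which
    makes the degenerate all-scores-equal case deterministically report
    sensitivity 0 / specificity 1.
    """
    scores, labels = _check_scores_labels(scores, labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.empty(0)
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        j = sens + spec - 1
        if j > best_j or (j == best_j and t > best_t):
            best_t, best_j = t, j
    return float(best_t)


def operating_point(scores, labels, threshold: float | None = None):
    """(threshold, sensitivity, specificity) at a decision threshold.

    When ``threshold`` is None it is chosen on the same data by Youden's
    J; in cross-validation the threshold should be chosen on the
    validation split and passed in here for the test split.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    pred = scores >= threshold
    sens = float(pred[labels == 1].mean())
    spec = float((~pred[labels == 0]).mean())
    return float(threshold), sens, spec


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    level: str  # "roi" | "patient"
    n_pos: int
    n_neg: int


def roc_result(scores, labels, threshold=None, level="roi") -> ROCResult:
    """Bundle AUC + CI + operating point for one score vector."""
    scores, labels = _check_scores_labels(scores, labels)
    a, lo, hi = delong_ci(scores, labels)
    thr, sens, spec = operating_point(scores, labels, threshold)
    return ROCResult(a, (lo, hi), sens, spec, thr, level,
                     int(labels.sum()), int((1 - labels).sum()))


# ---------------------------------------------------------------------------
# Patient-level aggregation
# ---------------------------------------------------------------------------

_AGG_RULES = {"max": np.max, "mean": np.mean, "min": np.min}


def patient_level_scores(patient_ids, scores, rule: str = "max"):
    """Aggregate per-ROI scores to one score per patient.

    The default ``max`` rule scores a patient by their most suspicious
    view, the usual clinical reading convention; ``mean`` and ``min``
    are available for sensitivity analyses. Returns
    ``(unique_patient_ids, aggregated_scores)`` with patients in first-
    appearance order.
    """
    if rule not in _AGG_RULES:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    patient_ids = np.asarray(patient_ids)
    scores = np.asarray(scores, dtype=float)
    if patient_ids.shape != scores.shape:
        raise ValueError("patient_ids and scores must align")
    order = {}
    for pid in patient_ids:
        order.setdefault(pid, len(order))
    agg = np.empty(len(order))
    fn = _AGG_RULES[rule]
    for pid, idx in order.items():
        agg[idx] = fn(scores[patient_ids == pid])
    return np.array(list(order)), agg


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Patient-level fold assignment with 3:1:1 rotations."""

    patient_ids: tuple
    fold_id: tuple[int, ...]
    k: int
    seed: int

    def folds(self) -> list[np.ndarray]:
        pid = np.asarray(self.patient_ids)
        fid = np.asarray(self.fold_id)
        return [pid[fid == f] for f in range(self.k)]

    def rotations(self):
        """Yield (train_ids, val_ids, test_ids) for each of k rotations."""
        folds = self.folds()
        for r in range(self.k):
            test = folds[r]
            val = folds[(r + 1) % self.k]
            train = np.concatenate(
                [folds[f] for f in range(self.k) if f not in (r, (r + 1) % self.k)]
            )
            yield train, val, test


def make_cv_plan(patient_ids, labels, k: int = 5, seed: int = 0,
                 max_retries: int = 100) -> CVPlan:
    """Stratified k-fold patient assignment for 3:1:1 rotations.

    Folds partition the patients with sizes equal up to 1 and are
    stratified by label. If stratification still leaves some fold
    without both classes (tiny cohorts), the draw is retried with a
    shifted seed up to ``max_retries`` times before raising.
    """
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels).astype(int)
    if patient_ids.size != labels.size:
        raise ValueError("patient_ids and labels must align")
    if np.unique(patient_ids).size != patient_ids.size:
        raise ValueError("patient_ids must be unique")
    if patient_ids.size < k:
        raise ValueError(f"need at least k={k} patients")
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        fold = np.empty(patient_ids.size, dtype=int)
        # deal each class round-robin over folds, rotating the starting
        # fold per class so remainders spread evenly
        start = 0
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            fold[idx] = (start + np.arange(idx.size)) % k
            start += idx.size
        ok = all(np.unique(labels[fold == f]).size == 2 for f in range(k))
        if ok:
            return CVPlan(tuple(patient_ids.tolist()), tuple(fold.tolist()), k, seed)
    raise ValueError(
        f"could not build {k} folds containing both classes after "
        f"{max_retries} retries; cohort too small or too unbalanced"
    )
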