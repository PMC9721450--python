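"""ROC/AUC, DeLong, operating points, CV plans."""

import numpy as np
import pytest
from scipy import stats

from periradiomics.evaluation import (
    auc,
    delong_ci,
    delong_test,
    make_cv_plan,
    operating_point,
    patient_level_scores,
    youden_threshold,
)


def pair_count_auc(scores, labels):
    """Exhaustive pair-counting oracle with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_delong_variance(sa, sb, labels):
    """Direct structural-component (V10/V01) computation."""
    sa, sb = np.asarray(sa, float), np.asarray(sb, float)
    labels = np.asarray(labels, int)
    out = []
    for s in (sa, sb):
        pos, neg = s[labels == 1], s[labels == 0]
        a = pair_count_auc(s, labels)
        v10 = np.array([np.mean([1.0 if p > n else 0.5 if p == n else 0.0
                                 for n in neg]) for p in pos])
        v01 = np.array([np.mean([1.0 if p > n else 0.5 if p == n else 0.0
                                 for p in pos]) for n in neg])
        out.append((a, v10, v01))
    (a1, v10_1, v01_1), (a2, v10_2, v01_2) = out
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    return a1, a2, var


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_examples():
    assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
    assert auc([0.9, 0.3, 0.4, 0.2], [1, 1, 0, 0]) == 0.75
    assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5


@pytest.mark.parametrize("seed", range(50))
def test_auc_equals_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 20)
    scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.7, 0.9], size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert auc(scores, labels) == pytest.approx(
        pair_count_auc(scores, labels), abs=1e-12)


def test_auc_single_class_raises():
    with pytest.raises(ValueError, match="both classes"):
        auc([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def test_delong_self_comparison_is_degenerate_p1():
    s = [0.9, 0.3, 0.4, 0.2, 0.6]
    y = [1, 1, 0, 0, 1]
    res = delong_test(s, s, y)
    assert res.z == 0.0 and res.p == 1.0 and res.degenerate


@pytest.mark.parametrize("seed", range(30))
def test_delong_variance_matches_structural_components(seed):
    rng = np.random.default_rng(100 + seed)
    n = rng.integers(5, 9)
    labels = rng.integers(0, 2, size=n)
    labels[:2] = 1  # guarantee >=2 per class
    labels[2:4] = 0
    sa = rng.random(n)
    sb = rng.random(n)
    res = delong_test(sa, sb, labels)
    a1, a2, var = brute_delong_variance(sa, sb, labels)
    assert res.auc_a == pytest.approx(a1, abs=1e-12)
    assert res.auc_b == pytest.approx(a2, abs=1e-12)
    if not res.degenerate:
        assert res.var_diff == pytest.approx(var, abs=1e-12)


def test_delong_symmetry():
    rng = np.random.default_rng(7)
    labels = np.array([1, 1, 1, 0, 0, 0, 1, 0])
    sa, sb = rng.random(8), rng.random(8)
    ab = delong_test(sa, sb, labels)
    ba = delong_test(sb, sa, labels)
    assert ab.z == pytest.approx(-ba.z, abs=1e-12)
    assert ab.p == pytest.approx(ba.p, abs=1e-12)


def test_delong_p_at_z_196():
    assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)


def test_delong_ci_contains_auc():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    scores = rng.random(40) + 0.3 * labels
    a, lo, hi = delong_ci(scores, labels)
    assert 0.0 <= lo <= a <= hi <= 1.0


# ---------------------------------------------------------------------------
# operating point
# ---------------------------------------------------------------------------

def test_operating_point_perfect_separation():
    thr, sens, spec = operating_point([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert sens == 1.0 and spec == 1.0


def test_operating_point_degenerate_all_equal():
    thr, sens, spec = operating_point([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert (sens, spec) == (0.0, 1.0)  # deterministic convention


@pytest.mark.parametrize("seed", range(20))
def test_youden_matches_exhaustive_sweep(seed):
    rng = np.random.default_rng(200 + seed)
    n = rng.integers(5, 15)
    scores = rng.choice(np.linspace(0, 1, 7), size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    thr = youden_threshold(scores, labels)
    pred = scores >= thr
    j_got = pred[labels == 1].mean() + (~pred[labels == 0]).mean() - 1
    best = max(
        ((scores >= t)[labels == 1].mean()
         + (~(scores >= t))[labels == 0].mean() - 1)
        for t in np.concatenate([scores - 1e-9, scores + 1e-9]))
    assert j_got == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# patient aggregation
# ---------------------------------------------------------------------------

def test_patient_aggregation_rules():
    pids = np.array(["a", "a", "b", "c", "c"])
    scores = np.array([0.2, 0.8, 0.5, 0.1, 0.4])
    ids, agg = patient_level_scores(pids, scores, "max")
    assert list(ids) == ["a", "b", "c"]
    assert agg.tolist() == [0.8, 0.5, 0.4]
    _, mean_agg = patient_level_scores(pids, scores, "mean")
    assert mean_agg.tolist() == [0.5, 0.5, 0.25]
    with pytest.raises(ValueError):
        patient_level_scores(pids, scores, "median")


def test_max_rule_dominates_min_rule_on_view_limited_signal():
    # malignancy visible in only one of the two views: the most-
    # suspicious-view (max) reading must be at least as discriminative
    rng = np.random.default_rng(5)
    n = 60
    labels = np.repeat(rng.integers(0, 2, size=n), 2)
    pids = np.repeat(np.arange(n), 2)
    scores = rng.random(2 * n) * 0.4
    visible = np.arange(2 * n) % 2 == 0
    scores[visible & (labels == 1)] += 0.6
    ids, smax = patient_level_scores(pids, scores, "max")
    _, smin = patient_level_scores(pids, scores, "min")
    plabels = labels[::2]
    assert auc(smax, plabels) >= auc(smin, plabels)


# ---------------------------------------------------------------------------
# CV plan
# ---------------------------------------------------------------------------

def test_cv_plan_partition_and_ratios():
    pids = [f"p{i}" for i in range(10)]
    labels = [0, 1] * 5
    plan = make_cv_plan(pids, labels, k=5, seed=0)
    rotations = list(plan.rotations())
    assert len(rotations) == 5
    all_test = np.concatenate([t for _, _, t in rotations])
    assert sorted(all_test.tolist()) == sorted(pids)  # each tested once
    for train, val, test in rotations:
        assert len(train) == 6 and len(val) == 2 and len(test) == 2
        assert not set(train) & set(val) | set(train) & set(test)


def test_cv_plan_stratified_and_deterministic():
    rng = np.random.default_rng(0)
    pids = [f"p{i}" for i in range(40)]
    labels = (rng.random(40) < 0.4).astype(int)
    a = make_cv_plan(pids, labels, k=5, seed=11)
    b = make_cv_plan(pids, labels, k=5, seed=11)
    assert a == b
    labels = np.asarray(labels)
    fold = np.asarray(a.fold_id)
    sizes = [int((fold == f).sum()) for f in range(5)]
    assert max(sizes) - min(sizes) <= 1
    for f in range(5):
        assert np.unique(labels[fold == f]).size == 2


def test_cv_plan_impossible_raises():
    with pytest.raises(ValueError):
        make_cv_plan(["a", "b", "c", "d", "e"], [1, 0, 0, 0, 0], k=5, seed=0)


# ---------------------------------------------------------------------------
# hypothesis property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=30),
       st.randoms(use_true_random=False))
def test_auc_pair_counting_property(scores, rnd):
    scores = np.asarray(scores, dtype=float)
    labels = np.array([rnd.randint(0, 1) for _ in scores])
    labels[:2] = [0, 1]
    assert auc(scores, labels) == pytest.approx(
        pair_count_auc(scores, labels), abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_delong_antisymmetry_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 20))
    labels = rng.integers(0, 2, size=n)
    labels[:2], labels[2:4] = 1, 0
    sa, sb = rng.random(n), rng.random(n)
    ab, ba = delong_test(sa, sb, labels), delong_test(sb, sa, labels)
    assert ab.z == pytest.approx(-ba.z, abs=1e-10)
    assert 0.0 <= ab.p <= 1.0
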