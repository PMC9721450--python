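"""Gray-level co-occurrence matrix (GLCM) features.

One symmetric, normalised co-occurrence matrix is built per angle at
the configured pixel distance; each feature is evaluated per angle and
averaged. Level indices are the 1-based discretized gray levels, and
``Ng`` below is the number of levels spanned by the region.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import FeatureConfig

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "Mcc",
)

_EPS = np.finfo(float).tiny


def glcm_matrices(levels, mask, config: FeatureConfig | None = None):
    """Per-angle symmetric normalised co-occurrence matrices.

    Returns ``(matrices, level_values)`` where ``matrices`` is a list
    aligned with ``config.angles`` (an all-zero matrix marks an angle
    with no valid pixel pair) and ``level_values`` the sorted distinct
    levels indexing the matrix rows/columns.
    """
    if config is None:
        config = FeatureConfig()
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    level_values = np.unique(levels[mask])
    ng = level_values.size
    index = np.full(levels.max() + 1 if levels.size else 1, -1, dtype=np.int64)
    index[level_values] = np.arange(ng)

    matrices = []
    for dr, dc in config.offsets():
        m = np.zeros((ng, ng))
        a_sl, b_sl = _offset_slices(levels.shape, dr, dc)
        valid = mask[a_sl] & mask[b_sl]
        if valid.any():
            a = index[levels[a_sl][valid]]
            b = index[levels[b_sl][valid]]
            np.add.at(m, (a, b), 1.0)
            m = m + m.T  # symmetric co-occurrence
            if config.normalize_matrices:
                m /= m.sum()
        matrices.append(m)
    return matrices, level_values


def _offset_slices(shape, dr, dc):
    """Slices (a, b) such that b is a shifted by (dr, dc)."""
    rows, cols = shape

    def ax(n, d):
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    ra, rb = ax(rows, dr)
    ca, cb = ax(cols, dc)
    return (ra, ca), (rb, cb)


def _features_one(p: np.ndarray, i_vals: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = i_vals.astype(float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())

    # p_{x+y} over sums, p_{x-y} over absolute differences
    sums = ii + jj
    diffs = np.abs(ii - jj)
    sum_vals = np.unique(sums)
    diff_vals = np.unique(diffs)
    p_sum = np.array([p[sums == s].sum() for s in sum_vals])
    p_diff = np.array([p[diffs == d].sum() for d in diff_vals])

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hx = ent(px)
    hxy = ent(p.ravel())
    outer = np.outer(px, px)
    pos = p > 0
    hxy1 = float(-(p[pos] * np.log2(outer[pos] + _EPS)).sum())
    opos = outer > 0
    hxy2 = float(-(outer[opos] * np.log2(outer[opos])).sum())

    da = float((p_diff * diff_vals).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    corr = 1.0 if sigma2 <= 0 else float(
        ((p * ii * jj).sum() - mu * mu) / sigma2)
    imc1 = 0.0 if hx == 0 else float((hxy - hxy1) / hx)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum()) if off.any() else 0.0

    # MCC: sqrt of second-largest eigenvalue of Q
    if ng == 1:
        mcc = 1.0
    else:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
        q = np.zeros((ng, ng))
        for k in range(ng):
            if px[k] > 0:
                q += np.outer(p[:, k], p[:, k]) / px[k]
        q = q / np.where(px[:, None] > 0, px[:, None], 1.0)
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if eig.size >= 2 else 1.0

    values = (
        float((p * ii * jj).sum()),                      # Autocorrelation
        mu,                                              # JointAverage
        float((p * (ii + jj - 2 * mu) ** 4).sum()),      # ClusterProminence
        float((p * (ii + jj - 2 * mu) ** 3).sum()),      # ClusterShade
        float((p * (ii + jj - 2 * mu) ** 2).sum()),      # ClusterTendency
        contrast,
        corr,
        da,                                              # DifferenceAverage
        ent(p_diff),                                     # DifferenceEntropy
        float((p_diff * (diff_vals - da) ** 2).sum()),   # DifferenceVariance
        float((p ** 2).sum()),                           # JointEnergy
        hxy,                                             # JointEntropy
        imc1, imc2,
        float((p / (1.0 + (ii - jj) ** 2)).sum()),       # Idm
        float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),  # Idmn
        float((p / (1.0 + np.abs(ii - jj))).sum()),      # Id
        float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),  # Idn
        inv_var,
        float(p.max()),                                  # MaximumProbability
        float((p_sum * sum_vals).sum()),                 # SumAverage
        ent(p_sum),                                      # SumEntropy
        float((p * (ii - mu) ** 2).sum()),               # SumSquares
        mcc,
    )
    return dict(zip(GLCM_NAMES, values))


def glcm_features(levels, mask, config: FeatureConfig | None = None):
    """Angle-averaged GLCM features; NaN for all if no angle has a
    valid in-mask pixel pair at the configured offset."""
    if config is None:
        config = FeatureConfig()
    matrices, level_values = glcm_matrices(levels, mask, config)
    per_angle = [_features_one(m, level_values) for m in matrices if m.sum() > 0]
    if not per_angle:
        warnings.warn("no valid pixel pairs for GLCM; features undefined",
                      stacklevel=2)
        return {name: float("nan") for name in GLCM_NAMES}
    return {name: float(np.mean([f[name] for f in per_angle]))
            for name in GLCM_NAMES}
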