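"""Gray-level run-length matrix (GLRLM) features.

A run is a maximal sequence of in-mask pixels of equal level along one
of the four directions (0/45/90/135 degrees); mask boundaries break
runs. One matrix ``R[level, length]`` is built per direction and each
feature is averaged over directions.
"""

from __future__ import annotations

import numpy as np

from .config import FeatureConfig

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)


def _lines(levels: np.ndarray, angle: int):
    """1D level lines for a direction; 0 encodes out-of-mask."""
    if angle == 0:
        return [levels[r] for r in range(levels.shape[0])]
    if angle == 90:
        return [levels[:, c] for c in range(levels.shape[1])]
    if angle == 45:  # anti-diagonals
        flipped = levels[:, ::-1]
        return [flipped.diagonal(k) for k in
                range(-flipped.shape[0] + 1, flipped.shape[1])]
    if angle == 135:
        return [levels.diagonal(k) for k in
                range(-levels.shape[0] + 1, levels.shape[1])]
    raise ValueError(f"unsupported angle {angle}")


def _runs_of_lines(lines):
    """(level, length) arrays of all runs with level > 0."""
    # concatenate lines with 0 separators, then find change points
    sep = np.zeros(1, dtype=np.int64)
    flat = np.concatenate([x for line in lines for x in (np.asarray(line), sep)])
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    vals = flat[starts]
    keep = vals > 0
    return vals[keep], lengths[keep]


def glrlm_matrices(levels, mask, config: FeatureConfig | None = None):
    """Per-direction run-length matrices.

    Returns ``(matrices, level_values, length_values)`` with matrices
    aligned to ``config.angles``. Rows index the distinct in-mask
    levels, columns the run lengths 1..max.
    """
    if config is None:
        config = FeatureConfig()
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    lv = np.where(mask, levels, 0)
    level_values = np.unique(levels[mask])
    index = np.full(int(lv.max()) + 1, -1, dtype=np.int64)
    index[level_values] = np.arange(level_values.size)

    per_dir = [_runs_of_lines(_lines(lv, a)) for a in config.angles]
    max_len = max(int(lengths.max()) for _, lengths in per_dir)
    matrices = []
    for vals, lengths in per_dir:
        m = np.zeros((level_values.size, max_len))
        np.add.at(m, (index[vals], lengths - 1), 1.0)
        matrices.append(m)
    length_values = np.arange(1, max_len + 1)
    return matrices, level_values, length_values


def _features_one(r, i_vals, l_vals, n_pixels):
    nr = r.sum()
    p = r / nr
    i = i_vals.astype(float)[:, None]
    ell = l_vals.astype(float)[None, :]
    ri = r.sum(axis=1)
    rl = r.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_l = float((p * ell).sum())
    pos = p[p > 0]
    values = (
        float((r / ell ** 2).sum() / nr),
        float((r * ell ** 2).sum() / nr),
        float((ri ** 2).sum() / nr),
        float((ri ** 2).sum() / nr ** 2),
        float((rl ** 2).sum() / nr),
        float((rl ** 2).sum() / nr ** 2),
        float(nr / n_pixels),
        float((p * (i - mu_i) ** 2).sum()),
        float((p * (ell - mu_l) ** 2).sum()),
        float(-(pos * np.log2(pos)).sum()),
        float((r / i ** 2).sum() / nr),
        float((r * i ** 2).sum() / nr),
        float((r / (i ** 2 * ell ** 2)).sum() / nr),
        float((r * i ** 2 / ell ** 2).sum() / nr),
        float((r * ell ** 2 / i ** 2).sum() / nr),
        float((r * i ** 2 * ell ** 2).sum() / nr),
    )
    return dict(zip(GLRLM_NAMES, values))


def glrlm_features(levels, mask, config: FeatureConfig | None = None):
    """Direction-averaged GLRLM features."""
    if config is None:
        config = FeatureConfig()
    mask = np.asarray(mask, dtype=bool)
    matrices, i_vals, l_vals = glrlm_matrices(levels, mask, config)
    n_pixels = int(mask.sum())
    per_dir = [_features_one(m, i_vals, l_vals, n_pixels) for m in matrices]
    return {name: float(np.mean([f[name] for f in per_dir]))
            for name in GLRLM_NAMES}
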