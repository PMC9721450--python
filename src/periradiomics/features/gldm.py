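"""Gray-level dependence matrix (GLDM) features.

The dependence size of an in-mask pixel is 1 (itself) plus the number
of its 8-neighbours that are inside the mask and whose level differs by
at most ``alpha`` (default 0, i.e. equal levels). ``D[level, size]``
counts pixels.
"""

from __future__ import annotations

import numpy as np

from .config import FeatureConfig
from .glcm import _offset_slices

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


def gldm_matrix(levels, mask, config: FeatureConfig | None = None):
    """Dependence matrix; returns (matrix, level_values, size_values)."""
    if config is None:
        config = FeatureConfig()
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for dr, dc in _NEIGHBOURS:
        a_sl, b_sl = _offset_slices(levels.shape, dr, dc)
        ok = (mask[a_sl] & mask[b_sl]
              & (np.abs(levels[a_sl] - levels[b_sl]) <= config.gldm_alpha))
        dep[a_sl] += ok
    size = dep[mask] + 1  # the pixel itself always belongs to its zone
    level_values = np.unique(levels[mask])
    index = np.full(int(levels[mask].max()) + 1, -1, dtype=np.int64)
    index[level_values] = np.arange(level_values.size)
    max_size = int(size.max())
    m = np.zeros((level_values.size, max_size))
    np.add.at(m, (index[levels[mask]], size - 1), 1.0)
    return m, level_values, np.arange(1, max_size + 1)


def gldm_features(levels, mask, config: FeatureConfig | None = None):
    mask = np.asarray(mask, dtype=bool)
    d, i_vals, j_vals = gldm_matrix(levels, mask, config)
    nz = d.sum()  # equals the number of in-mask pixels
    p = d / nz
    i = i_vals.astype(float)[:, None]
    j = j_vals.astype(float)[None, :]
    di = d.sum(axis=1)
    dj = d.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pos = p[p > 0]
    values = (
        float((d / j ** 2).sum() / nz),
        float((d * j ** 2).sum() / nz),
        float((di ** 2).sum() / nz),
        float((dj ** 2).sum() / nz),
        float((dj ** 2).sum() / nz ** 2),
        float((p * (i - mu_i) ** 2).sum()),
        float((p * (j - mu_j) ** 2).sum()),
        float(-(pos * np.log2(pos)).sum()),
        float((d / i ** 2).sum() / nz),
        float((d * i ** 2).sum() / nz),
        float((d / (i ** 2 * j ** 2)).sum() / nz),
        float((d * i ** 2 / j ** 2).sum() / nz),
        float((d * j ** 2 / i ** 2).sum() / nz),
        float((d * i ** 2 * j ** 2).sum() / nz),
    )
    return dict(zip(GLDM_NAMES, values))
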