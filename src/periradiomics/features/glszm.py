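"""Gray-level size-zone matrix (GLSZM) features.

A zone is an 8-connected component of in-mask pixels sharing one gray
level; the matrix ``S[level, size]`` counts zones. GLSZM has no
direction, so a single matrix is built.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import FeatureConfig

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

_STRUCT8 = np.ones((3, 3), dtype=bool)


def glszm_matrix(levels, mask, config: FeatureConfig | None = None):
    """Size-zone matrix; returns (matrix, level_values, size_values)."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    level_values = np.unique(levels[mask])
    zones: list[tuple[int, int]] = []  # (level-index, size)
    for li, level in enumerate(level_values):
        lab, n = ndimage.label((levels == level) & mask, structure=_STRUCT8)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((li, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    m = np.zeros((level_values.size, max_size))
    for li, s in zones:
        m[li, s - 1] += 1.0
    return m, level_values, np.arange(1, max_size + 1)


def glszm_features(levels, mask, config: FeatureConfig | None = None):
    mask = np.asarray(mask, dtype=bool)
    s, i_vals, s_vals = glszm_matrix(levels, mask, config)
    nz = s.sum()
    n_pixels = int(mask.sum())
    p = s / nz
    i = i_vals.astype(float)[:, None]
    z = s_vals.astype(float)[None, :]
    si = s.sum(axis=1)
    sz = s.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_z = float((p * z).sum())
    pos = p[p > 0]
    values = (
        float((s / z ** 2).sum() / nz),
        float((s * z ** 2).sum() / nz),
        float((si ** 2).sum() / nz),
        float((si ** 2).sum() / nz ** 2),
        float((sz ** 2).sum() / nz),
        float((sz ** 2).sum() / nz ** 2),
        float(nz / n_pixels),
        float((p * (i - mu_i) ** 2).sum()),
        float((p * (z - mu_z) ** 2).sum()),
        float(-(pos * np.log2(pos)).sum()),
        float((s / i ** 2).sum() / nz),
        float((s * i ** 2).sum() / nz),
        float((s / (i ** 2 * z ** 2)).sum() / nz),
        float((s * i ** 2 / z ** 2).sum() / nz),
        float((s * z ** 2 / i ** 2).sum() / nz),
        float((s * i ** 2 * z ** 2).sum() / nz),
    )
    return dict(zip(GLSZM_NAMES, values))
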