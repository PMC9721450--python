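"""Gray-level discretization of in-mask intensities."""

from __future__ import annotations

import numpy as np

from .config import FeatureConfig


def discretize(image, mask, config: FeatureConfig | None = None) -> np.ndarray:
    """Map in-mask intensities to integer gray levels starting at 1.

    Fixed bin width ``w``: ``level = floor((v - min) / w) + 1``.
    Fixed bin count ``n``: ``n`` equal-width bins over the in-mask
    range, top edge inclusive. A constant region yields a single
    level 1 in either mode.

    Returns an integer array of the image shape with 0 outside the
    mask.
    """
    if config is None:
        config = FeatureConfig()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=np.int64)
    if config.discretization == "fixed_bin_width":
        w = float(config.bin_value)
        levels[mask] = np.floor((vals - lo) / w).astype(np.int64) + 1
    else:
        n = int(config.bin_value)
        if hi == lo:
            levels[mask] = 1
        else:
            lv = np.floor((vals - lo) / ((hi - lo) / n)).astype(np.int64) + 1
            levels[mask] = np.minimum(lv, n)
    return levels
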