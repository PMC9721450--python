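"""Full feature-vector extraction for one (image, mask) pair."""

from __future__ import annotations

import numpy as np

from .config import FeatureConfig
from .discretize import discretize
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .glcm import GLCM_NAMES, glcm_features
from .gldm import GLDM_NAMES, gldm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .shape2d import SHAPE2D_NAMES, shape2d_features


class EmptyRegionError(ValueError):
    """Raised when feature extraction is requested on an empty mask."""


def feature_names(include_shape: bool = True) -> list[str]:
    """Stable, ordered names of every feature the engine computes."""
    names = []
    if include_shape:
        names += [f"shape2d.{n}" for n in SHAPE2D_NAMES]
    names += [f"firstorder.{n}" for n in FIRST_ORDER_NAMES]
    names += [f"glcm.{n}" for n in GLCM_NAMES]
    names += [f"glrlm.{n}" for n in GLRLM_NAMES]
    names += [f"glszm.{n}" for n in GLSZM_NAMES]
    names += [f"gldm.{n}" for n in GLDM_NAMES]
    return names


def _bbox(mask: np.ndarray, pad: int = 1):
    rr, cc = np.nonzero(mask)
    r0, r1 = max(rr.min() - pad, 0), min(rr.max() + pad + 1, mask.shape[0])
    c0, c1 = max(cc.min() - pad, 0), min(cc.max() + pad + 1, mask.shape[1])
    return slice(r0, r1), slice(c0, c1)


def extract_all(image, mask, spacing_mm=(1.0, 1.0),
                config: FeatureConfig | None = None,
                include_shape: bool = True) -> dict[str, float]:
    """All feature classes on one region, as an ordered name->value dict.

    The image is cropped to the mask bounding box before the texture
    matrices are built (features are mask-local, so this is exact and
    keeps large images cheap). Deterministic: identical inputs yield
    identical vectors.
    """
    if config is None:
        config = FeatureConfig()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise EmptyRegionError("cannot extract features from an empty mask")
    sl = _bbox(mask)
    img, msk = image[sl], mask[sl]
    levels = discretize(img, msk, config)

    out: dict[str, float] = {}
    if include_shape:
        for k, v in shape2d_features(msk, spacing_mm).items():
            out[f"shape2d.{k}"] = v
    for k, v in first_order_features(img, msk, config).items():
        out[f"firstorder.{k}"] = v
    for k, v in glcm_features(levels, msk, config).items():
        out[f"glcm.{k}"] = v
    for k, v in glrlm_features(levels, msk, config).items():
        out[f"glrlm.{k}"] = v
    for k, v in glszm_features(levels, msk, config).items():
        out[f"glszm.{k}"] = v
    for k, v in gldm_features(levels, msk, config).items():
        out[f"gldm.{k}"] = v
    return out
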