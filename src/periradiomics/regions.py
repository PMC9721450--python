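"""Tumoral / peritumoral-ring / combined region construction.

The peritumoral ring at distance ``d`` mm is built by thresholding the
Euclidean distance transform of the tumour mask at ``d`` (exact
physical-unit dilation, valid under anisotropic pixel spacing),
subtracting the tumour, and intersecting with the *body mask* (breast
plus pectoral muscle, from Otsu thresholding) so that no ring pixel
falls on the air background. The combined region is the tumour union
its ring. Tumour pixels are kept in the combined region even where the
body mask disagrees: the manual lesion mask wins that tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "BodyMask",
    "RegionSet",
    "compute_body_mask",
    "dilate_mask",
    "build_region_set",
    "DEFAULT_DISTANCES_MM",
]

DEFAULT_DISTANCES_MM = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class BodyMask:
    pixels: np.ndarray


@dataclass(frozen=True)
class RegionSet:
    """Tumour plus per-distance ring and combined masks."""

    tumor: np.ndarray
    distances_mm: tuple[float, ...]
    rings: dict[float, np.ndarray] = field(repr=False)
    combineds: dict[float, np.ndarray] = field(repr=False)
    body: np.ndarray = field(repr=False, default=None)
    empty_distances: tuple[float, ...] = ()

    def region(self, kind: str, distance_mm: float | None = None) -> np.ndarray:
        """Look up a region by kind: tumoral | peritumoral | combined."""
        if kind == "tumoral":
            return self.tumor
        if kind == "peritumoral":
            return self.rings[distance_mm]
        if kind == "combined":
            return self.combineds[distance_mm]
        raise ValueError(f"unknown region kind {kind!r}")


def compute_body_mask(image, min_area_fraction: float = 0.005) -> BodyMask:
    """Breast + pectoral support by Otsu thresholding.

    Pixels above the Otsu threshold are kept; connected components
    smaller than ``min_area_fraction`` of the image (stray bright
    specks) are dropped and holes are filled. Raises on a constant
    image, where no threshold exists.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    if np.ptp(pixels) == 0:
        raise ValueError("Otsu threshold undefined: image is constant")
    mask = pixels > threshold_otsu(pixels)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        keep = np.flatnonzero(sizes >= min_area_fraction * pixels.size) + 1
        mask = np.isin(lab, keep)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("Otsu body mask is empty")
    return BodyMask(mask)


def dilate_mask(mask, distance_mm: float, spacing_mm) -> np.ndarray:
    """Pixels within ``distance_mm`` (Euclidean, physical units) of the
    mask, including the mask itself. ``spacing_mm`` may be a scalar or
    per-axis (row, col); distance 0 returns the input."""
    pixels = np.asarray(getattr(mask, "pixels", mask), dtype=bool)
    if distance_mm < 0:
        raise ValueError("distance_mm must be >= 0")
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, pixels.ndim)
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    if distance_mm == 0:
        return pixels.copy()
    dist = ndimage.distance_transform_edt(~pixels, sampling=tuple(spacing))
    return dist <= distance_mm


def build_region_set(image, tumor, distances_mm=DEFAULT_DISTANCES_MM,
                     body: BodyMask | None = None) -> RegionSet:
    """Rings and combined regions at each distance.

    ``ring(d) = (dilate(tumor, d) \\ tumor) & body`` and
    ``combined(d) = (dilate(tumor, d) & body) | tumor``. A ring that is
    empty after the body intersection is flagged in
    ``empty_distances`` (with a warning) so downstream modelling can
    skip it.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    spacing = getattr(image, "spacing_mm", (1.0, 1.0))
    tumor_px = np.asarray(getattr(tumor, "pixels", tumor), dtype=bool)
    if tumor_px.shape != pixels.shape:
        raise ValueError("tumor mask and image shapes differ")
    if not tumor_px.any():
        raise ValueError("tumor mask is empty")
    if body is None:
        body = compute_body_mask(pixels)
    body_px = body.pixels

    rings: dict[float, np.ndarray] = {}
    combineds: dict[float, np.ndarray] = {}
    empty = []
    for d in distances_mm:
        dil = dilate_mask(tumor_px, float(d), spacing)
        ring = dil & ~tumor_px & body_px
        rings[float(d)] = ring
        combineds[float(d)] = (dil & body_px) | tumor_px
        if not ring.any():
            empty.append(float(d))
            warnings.warn(
                f"peritumoral ring at {d} mm is empty after body-mask "
                "intersection", stacklevel=2)
    return RegionSet(tumor=tumor_px,
                     distances_mm=tuple(float(d) for d in distances_mm),
                     rings=rings, combineds=combineds, body=body_px,
                     empty_distances=tuple(empty))
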