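"""2D shape descriptors of a binary mask in physical units."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

SHAPE2D_NAMES = (
    "Area", "Perimeter", "PerimeterToArea", "MajorAxisLength",
    "MinorAxisLength", "Elongation", "Eccentricity", "Circularity",
    "MaximumDiameter",
)


def _contour_perimeter(mask: np.ndarray, spacing) -> float:
    """Boundary length of the 0.5-level contour, in mm.

    Marching squares on a zero-padded mask handles anisotropic spacing
    by scaling contour coordinates before summing segment lengths.
    """
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        seg = np.diff(contour, axis=0) * np.asarray(spacing)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def _boundary_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    inner = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    boundary = mask & ~inner
    rr, cc = np.nonzero(boundary)
    return np.column_stack([rr * spacing[0], cc * spacing[1]])


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    try:  # convex hull keeps the pairwise scan tiny for large masks
        from scipy.spatial import ConvexHull
        if len(points) > 3:
            points = points[ConvexHull(points).vertices]
    except Exception:  # collinear or degenerate point sets
        pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape2d_features(mask, spacing_mm) -> dict[str, float]:
    """Shape features of a 2D mask with (row, col) pixel spacing in mm.

    Axis lengths follow the ellipse-of-inertia convention
    ``4 * sqrt(eigenvalue)`` of the pixel-coordinate covariance;
    elongation is minor/major axis ratio (1 = round, -> 0 elongated)
    and circularity is ``2 * sqrt(pi * area) / perimeter`` (1 for a
    disk).
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.size == 1:
        spacing = np.repeat(spacing, 2)
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    if not mask.any():
        raise ValueError("mask is empty")

    pixel_area = float(spacing[0] * spacing[1])
    area = mask.sum() * pixel_area
    perimeter = _contour_perimeter(mask, spacing)

    rr, cc = np.nonzero(mask)
    coords = np.column_stack([rr * spacing[0], cc * spacing[1]])
    cov = np.cov(coords, rowvar=False) if len(coords) > 1 else np.zeros((2, 2))
    eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0, None))
    minor, major = 4 * np.sqrt(eig[0]), 4 * np.sqrt(eig[1])
    elongation = float(minor / major) if major > 0 else 1.0
    eccentricity = float(np.sqrt(1 - (minor / major) ** 2)) if major > 0 else 0.0

    values = (
        area, perimeter, perimeter / area, float(major), float(minor),
        elongation, eccentricity,
        float(2 * np.sqrt(np.pi * area) / perimeter) if perimeter > 0 else 0.0,
        _max_pairwise_distance(_boundary_points_mm(mask, spacing)),
    )
    return dict(zip(SHAPE2D_NAMES, values))
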