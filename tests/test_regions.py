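"""Body-mask extraction and physical-unit ring construction."""

import numpy as np
import pytest

from periradiomics import phantom
from periradiomics.regions import (
    build_region_set,
    compute_body_mask,
    dilate_mask,
)


@pytest.fixture(scope="module")
def mlo_case():
    cfg = phantom.PhantomConfig(n_patients=2, seed=42)
    cases = phantom.generate_dataset(cfg)
    return next(c for c in cases if c.image.view == "MLO")


# ---------------------------------------------------------------------------
# body mask
# ---------------------------------------------------------------------------

def test_body_mask_exact_on_bimodal_image():
    img = np.zeros((30, 30))
    img[5:25, 5:20] = 1000.0
    mask = compute_body_mask(img).pixels
    assert np.array_equal(mask, img > 0)


def test_body_mask_covers_breast_and_wedge(mlo_case):
    got = compute_body_mask(mlo_case.image.pixels).pixels
    truth = mlo_case.body_support
    dice = 2 * (got & truth).sum() / (got.sum() + truth.sum())
    assert dice >= 0.99
    # wedge specifically is retained
    wedge = truth & ~mlo_case.breast_support
    assert wedge.any() and (got & wedge).sum() / wedge.sum() > 0.95


def test_body_mask_constant_image_raises():
    with pytest.raises(ValueError, match="Otsu"):
        compute_body_mask(np.full((10, 10), 3.0))


# ---------------------------------------------------------------------------
# dilation
# ---------------------------------------------------------------------------

def test_dilate_zero_distance_is_identity():
    rng = np.random.default_rng(0)
    mask = rng.random((12, 12)) < 0.3
    mask[6, 6] = True
    assert np.array_equal(dilate_mask(mask, 0.0, 1.0), mask)


def test_dilate_single_pixel_disk():
    mask = np.zeros((11, 11), bool)
    mask[5, 5] = True
    out = dilate_mask(mask, 2.0, 1.0)
    # brute-force enumeration of offsets with dr^2 + dc^2 <= 4
    expected = np.zeros_like(mask)
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            if dr * dr + dc * dc <= 4:
                expected[5 + dr, 5 + dc] = True
    assert np.array_equal(out, expected)
    assert out.sum() == 13


def test_dilate_monotone_in_distance():
    rng = np.random.default_rng(1)
    mask = rng.random((20, 20)) < 0.1
    mask[10, 10] = True
    for d1, d2 in [(0.5, 1.0), (1.0, 3.0), (2.0, 2.0)]:
        a = dilate_mask(mask, d1, 0.7)
        b = dilate_mask(mask, d2, 0.7)
        assert (a <= b).all()


def test_dilate_anisotropic_spacing():
    mask = np.zeros((21, 21), bool)
    mask[10, 10] = True
    out = dilate_mask(mask, 2.0, (2.0, 1.0))  # rows cost 2 mm, cols 1 mm
    assert out[10, 12] and out[11, 10]
    assert not out[12, 10]  # 4 mm away along rows


# ---------------------------------------------------------------------------
# region sets
# ---------------------------------------------------------------------------

def circle_image(radius_px=10, size=64):
    rr, cc = np.indices((size, size))
    tumor = (rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= radius_px ** 2
    img = np.zeros((size, size))
    img[2:-2, 2:-2] = 500.0  # bright body with a thin dark border
    return img, tumor


def test_ring_set_algebra_and_annulus_area():
    img, tumor = circle_image(radius_px=10)

    class FakeImage:
        pixels = img
        spacing_mm = (1.0, 1.0)

    rs = build_region_set(FakeImage, tumor, distances_mm=[2.0, 3.0, 5.0])
    ring2, comb2 = rs.rings[2.0], rs.combineds[2.0]
    assert not (ring2 & tumor).any()
    assert np.array_equal(comb2, tumor | ring2)
    assert comb2.sum() - tumor.sum() == ring2.sum()
    ring3 = rs.rings[3.0]
    assert (ring2 <= ring3).all()  # nesting over distances
    # discrete ring area vs the analytic annulus pi((r+d)^2 - r^2)
    analytic = np.pi * (15.0 ** 2 - 10.0 ** 2)
    assert rs.rings[5.0].sum() == pytest.approx(analytic, rel=0.05)


def test_ring_excludes_background_for_edge_tumor(mlo_case):
    img, lesion = mlo_case.image, mlo_case.mask
    # drag the tumour to the breast boundary by shifting it right
    breast = mlo_case.breast_support
    tumor = lesion.pixels
    cols = np.nonzero(tumor.any(axis=0))[0]
    shift = int(breast.shape[1] - cols.max() - 2)
    shifted = np.roll(tumor, shift, axis=1)
    shifted &= breast  # clip to keep the lesion inside the body
    rs = build_region_set(img, shifted, distances_mm=[3.0])
    body = rs.body
    assert (rs.rings[3.0] <= body).all()
    assert (rs.combineds[3.0] <= (body | shifted)).all()


def test_halving_spacing_doubles_ring_thickness():
    img, tumor = circle_image(radius_px=10)

    class Coarse:
        pixels = img
        spacing_mm = (1.0, 1.0)

    class Fine:
        pixels = img
        spacing_mm = (0.5, 0.5)

    thick = {}
    for im, name in ((Coarse, "coarse"), (Fine, "fine")):
        rs = build_region_set(im, tumor, distances_mm=[3.0])
        row = rs.rings[3.0][32]
        thick[name] = row[:32].sum()  # one-sided radial thickness in px
    assert abs(thick["fine"] - 2 * thick["coarse"]) <= 1


def test_region_set_deterministic(mlo_case):
    img, lesion = mlo_case.image, mlo_case.mask
    a = build_region_set(img, lesion, distances_mm=[1.0, 2.0])
    b = build_region_set(img, lesion, distances_mm=[1.0, 2.0])
    for d in (1.0, 2.0):
        assert np.array_equal(a.rings[d], b.rings[d])
        assert np.array_equal(a.combineds[d], b.combineds[d])


# ---------------------------------------------------------------------------
# hypothesis property test
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 4.0), st.floats(0.1, 4.0))
def test_dilation_monotone_property(seed, d1, d2):
    rng = np.random.default_rng(seed)
    mask = rng.random((15, 15)) < 0.15
    mask[7, 7] = True
    lo, hi = sorted((d1, d2))
    spacing = float(rng.uniform(0.3, 2.0))
    a = dilate_mask(mask, lo, spacing)
    b = dilate_mask(mask, hi, spacing)
    assert (a <= b).all()
    assert (mask <= a).all()
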