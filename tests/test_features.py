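"""Feature engine vs independent brute-force oracles, plus the engine's
structural invariants (rotation consistency, mask locality,
determinism)."""

import numpy as np
import pytest

from periradiomics.features import (
    FeatureConfig,
    discretize,
    extract_all,
    feature_names,
    first_order_features,
    glcm_features,
    glcm_matrices,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glszm_features,
    glszm_matrix,
    EmptyRegionError,
    shape2d_features,
)
from periradiomics.features.gldm import GLDM_NAMES
from periradiomics.features.glrlm import GLRLM_NAMES
from periradiomics.features.glszm import GLSZM_NAMES

import _oracles as orc

CFG = FeatureConfig()


def random_region(rng, max_side=8, n_levels=5):
    """Random small level image + random (nonempty, >=2 px) mask."""
    h = rng.integers(2, max_side + 1)
    w = rng.integers(2, max_side + 1)
    levels = rng.integers(1, n_levels + 1, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    if mask.sum() < 2:
        mask[rng.integers(h), rng.integers(w)] = True
        mask[0, 0] = True
    return levels, mask


REGIONS = [random_region(np.random.default_rng(1000 + i)) for i in range(120)]


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_discretize_fixed_bin_width_examples():
    img = np.array([[0.0, 10.0, 20.0]])
    mask = np.ones_like(img, dtype=bool)
    out = discretize(img, mask, FeatureConfig(bin_value=10))
    assert out.tolist() == [[1, 2, 3]]
    const = discretize(np.full((3, 3), 7.0), np.ones((3, 3), bool), CFG)
    assert set(const.ravel()) == {1}


@pytest.mark.parametrize("idx", range(0, 120, 7))
def test_discretize_matches_per_pixel_loop(idx):
    rng = np.random.default_rng(idx)
    img = rng.normal(100, 40, size=(6, 6))
    mask = rng.random((6, 6)) < 0.7
    mask[2, 2] = True
    got = discretize(img, mask, FeatureConfig(bin_value=25.0))
    expected = orc.oracle_discretize_fbw(img, mask, 25.0)
    assert np.array_equal(got[mask], expected[mask])


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def test_first_order_trivial_regions():
    const = np.full((4, 4), 5.0)
    f = first_order_features(const, np.ones((4, 4), bool), CFG)
    assert f["Variance"] == 0 and f["Entropy"] == 0 and f["Uniformity"] == 1
    quad = np.array([[1.0, 2.0], [3.0, 4.0]])
    f = first_order_features(quad, np.ones((2, 2), bool), CFG)
    assert f["Mean"] == 2.5 and f["Range"] == 3


@pytest.mark.parametrize("idx", range(20))
def test_first_order_matches_direct_formulas(idx):
    rng = np.random.default_rng(2000 + idx)
    img = rng.normal(50, 20, size=(5, 5))
    mask = rng.random((5, 5)) < 0.8
    mask[0, :2] = True
    got = first_order_features(img, mask, CFG)
    lv = discretize(img, mask, CFG)[mask]
    expected = orc.oracle_first_order(img[mask], lv.tolist())
    assert set(got) == set(expected)
    for name in got:
        assert got[name] == pytest.approx(expected[name], abs=1e-9), name


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_shape_area_scales_with_spacing():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    assert shape2d_features(mask, (1.0, 1.0))["Area"] == pytest.approx(100.0)
    assert shape2d_features(mask, (0.5, 0.5))["Area"] == pytest.approx(25.0)


def test_shape_elongation_of_ellipse():
    rr, cc = np.indices((60, 60))
    mask = ((rr - 30) / 20.0) ** 2 + ((cc - 30) / 10.0) ** 2 <= 1
    f = shape2d_features(mask, (1.0, 1.0))
    assert f["Elongation"] == pytest.approx(0.5, rel=0.05)
    assert f["MajorAxisLength"] == pytest.approx(40.0, rel=0.05)
    assert f["MaximumDiameter"] == pytest.approx(40.0, rel=0.05)
    assert f["Circularity"] <= 1.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_glcm_two_by_two_example():
    levels = np.array([[1, 1], [1, 2]])
    mask = np.ones((2, 2), bool)
    cfg = FeatureConfig(angles=(0,))
    (m,), vals = glcm_matrices(levels, mask, cfg)
    assert m[0, 0] == pytest.approx(0.5)
    assert m[0, 1] == pytest.approx(0.25) and m[1, 0] == pytest.approx(0.25)
    f = glcm_features(levels, mask, cfg)
    assert f["Contrast"] == pytest.approx(0.5)


def test_glcm_constant_region():
    f = glcm_features(np.ones((3, 3), int), np.ones((3, 3), bool), CFG)
    assert f["Contrast"] == 0 and f["JointEntropy"] == 0


@pytest.mark.parametrize("idx", range(0, 120))
def test_glcm_matches_pair_enumeration_oracle(idx):
    levels, mask = REGIONS[idx]
    got = glcm_features(levels, mask, CFG)
    per_angle = []
    for angle in CFG.angles:
        m, vals = orc.oracle_glcm_matrix(levels, mask, angle)
        if m.sum() > 0:
            per_angle.append(orc.oracle_glcm_features(m, vals))
    if not per_angle:
        assert all(np.isnan(v) for v in got.values())
        return
    for name in got:
        expected = np.mean([f[name] for f in per_angle])
        assert got[name] == pytest.approx(expected, abs=1e-9), name


# ---------------------------------------------------------------------------
# GLRLM / GLSZM / GLDM
# ---------------------------------------------------------------------------

def test_glrlm_run_scan_example():
    levels = np.array([[1, 1, 2], [2, 2, 2], [3, 3, 3]])
    runs = orc.oracle_glrlm_runs(levels, np.ones((3, 3), bool), 0)
    assert sorted(runs) == [(1, 2), (2, 1), (2, 3), (3, 3)]


@pytest.mark.parametrize("idx", range(0, 120))
def test_glrlm_matches_run_scan_oracle(idx):
    levels, mask = REGIONS[idx]
    got = glrlm_features(levels, mask, CFG)
    per_dir = [orc.oracle_glrlm_features(levels, mask, a, GLRLM_NAMES)[1]
               for a in CFG.angles]
    for name in got:
        expected = np.mean([f[name] for f in per_dir])
        assert got[name] == pytest.approx(expected, abs=1e-9), name


def test_glszm_constant_region_single_zone():
    levels = np.ones((3, 4), int)
    m, _, sizes = glszm_matrix(levels, np.ones((3, 4), bool), CFG)
    assert m.sum() == 1 and m[0, -1] == 1 and sizes[-1] == 12


@pytest.mark.parametrize("idx", range(0, 120))
def test_glszm_matches_flood_fill_oracle(idx):
    levels, mask = REGIONS[idx]
    got = glszm_features(levels, mask, CFG)
    zones = orc.oracle_glszm_zones(levels, mask)
    _, expected = orc.zones_to_features(zones, int(mask.sum()), GLSZM_NAMES)
    for name in got:
        assert got[name] == pytest.approx(expected[name], abs=1e-9), name


@pytest.mark.parametrize("idx", range(0, 120))
def test_gldm_matches_neighbour_loop_oracle(idx):
    levels, mask = REGIONS[idx]
    got = gldm_features(levels, mask, CFG)
    entries = orc.oracle_gldm_entries(levels, mask, alpha=CFG.gldm_alpha)
    _, expected = orc.zones_to_features(entries, int(mask.sum()), GLDM_NAMES,
                                        keys=orc.KEYS_GLDM)
    for name in got:
        assert got[name] == pytest.approx(expected[name], abs=1e-9), name


def test_gldm_matrix_counts_every_pixel_once():
    levels, mask = REGIONS[0]
    m, _, _ = gldm_matrix(levels, mask, CFG)
    assert m.sum() == mask.sum()


# ---------------------------------------------------------------------------
# engine invariants
# ---------------------------------------------------------------------------

def test_rotation_consistency_of_angle_averaged_features():
    rng = np.random.default_rng(9)
    img = rng.normal(100, 30, size=(12, 12))
    mask = rng.random((12, 12)) < 0.85
    mask[5, 5] = True
    base = extract_all(img, mask, (1.0, 1.0), CFG, include_shape=False)
    rot = extract_all(np.rot90(img), np.rot90(mask), (1.0, 1.0), CFG,
                      include_shape=False)
    for name, v in base.items():
        assert rot[name] == pytest.approx(v, abs=1e-9), name


def test_mask_locality():
    rng = np.random.default_rng(10)
    img = rng.normal(100, 30, size=(10, 10))
    mask = np.zeros((10, 10), bool)
    mask[3:7, 3:7] = True
    base = extract_all(img, mask, (1.0, 1.0), CFG)
    tampered = img.copy()
    tampered[~mask] = rng.normal(500, 100, size=int((~mask).sum()))
    after = extract_all(tampered, mask, (1.0, 1.0), CFG)
    assert base == after


def test_extract_all_complete_and_deterministic():
    rng = np.random.default_rng(11)
    img = rng.normal(100, 30, size=(15, 15))
    mask = rng.random((15, 15)) < 0.7
    mask[7, 7] = mask[7, 8] = True
    v1 = extract_all(img, mask, (0.5, 0.5), CFG)
    v2 = extract_all(img, mask, (0.5, 0.5), CFG)
    assert v1 == v2
    assert list(v1) == feature_names()
    assert len(v1) == 9 + 18 + 24 + 16 + 16 + 14
    assert all(np.isfinite(v) for v in v1.values())


def test_extract_all_empty_mask_raises():
    with pytest.raises(EmptyRegionError):
        extract_all(np.ones((4, 4)), np.zeros((4, 4), bool))
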