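"""Phenotypic features: color statistics, co-occurrence texture, geometry."""

import numpy as np
import pytest
from skimage.draw import disk

from plantnni.features import (
    FEATURE_NAMES,
    COLOR_FEATURES,
    GEOMETRY_FEATURES,
    TEXTURE_FEATURES,
    CalibrationScale,
    GLCMParams,
    PhenotypeExtractor,
    color_features,
    extract_all,
    geometry_features,
    texture_features,
)
from plantnni.reference import PRESET_23


def test_feature_names_order_and_count():
    assert len(FEATURE_NAMES) == 65
    assert FEATURE_NAMES[:45] == COLOR_FEATURES
    assert FEATURE_NAMES[45:51] == TEXTURE_FEATURES
    assert FEATURE_NAMES[51:] == GEOMETRY_FEATURES
    assert set(PRESET_23) <= set(FEATURE_NAMES)


# ---------------------------------------------------------------- color


def test_color_stats_uniform_region():
    img = np.full((6, 6, 3), 100, dtype=np.uint8)
    mask = np.ones((6, 6), dtype=bool)
    out = color_features(img, mask)
    for ch in "RGBV":
        assert out[f"{ch}_std"] == 0.0
        assert out[f"{ch}_range"] == 0.0
        assert out[f"{ch}_cv"] == 0.0


def test_color_stats_two_pixel_hand_arithmetic():
    img = np.zeros((1, 2, 3), dtype=np.uint8)
    img[0, 0, 0], img[0, 1, 0] = 10, 30
    mask = np.ones((1, 2), dtype=bool)
    out = color_features(img, mask)
    assert out["R_mean"] == 20.0
    assert out["R_std"] == 10.0  # population std
    assert out["R_median"] == 20.0
    assert out["R_range"] == 20.0
    assert out["R_cv"] == 0.5


def test_color_empty_mask_raises():
    with pytest.raises(ValueError):
        color_features(np.zeros((3, 3, 3), np.uint8), np.zeros((3, 3), bool))


def test_hue_reflects_greenness_direction():
    """Deeper green (larger hue on the half-scale) for higher greenness."""
    from plantnni.synthetic import LatentPlantState, render_plant

    means = []
    for g in (0.2, 0.8):
        state = LatentPlantState(0.5, 60.0, 0.9, g, 0.0, 8, 50.0)
        s = render_plant(state, seed=1)
        means.append(color_features(s.image, s.truth_mask)["H_mean"])
    assert means[1] > means[0]


# --------------------------------------------------------------- texture


def _glcm_oracle(gray, mask, distance=1, levels=256):
    """Exhaustive pair enumeration at the four canonical offsets."""
    offsets = {0: (0, distance), 45: (-distance, distance),
               90: (-distance, 0), 135: (-distance, -distance)}
    q = np.floor(gray * levels / 256.0).astype(int).clip(0, levels - 1)
    mats = []
    H, W = gray.shape
    for dr, dc in offsets.values():
        counts = np.zeros((levels, levels))
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1  # symmetric
        if counts.sum() > 0:
            mats.append(counts / counts.sum())
    p = np.mean(mats, axis=0)
    i, j = np.indices(p.shape)
    contrast = (p * (i - j) ** 2).sum()
    dissimilarity = (p * np.abs(i - j)).sum()
    homogeneity = (p / (1.0 + (i - j) ** 2)).sum()
    asm = (p**2).sum()
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    var_i = ((i - mu_i) ** 2 * p).sum()
    var_j = ((j - mu_j) ** 2 * p).sum()
    if var_i > 0 and var_j > 0:
        corr = (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
    else:
        corr = 1.0
    return {"contrast": contrast, "dissimilarity": dissimilarity,
            "homogeneity": homogeneity, "energy": np.sqrt(asm),
            "correlation": corr, "ASM": asm}


def _gray_image(gray):
    """RGB image whose BT.601 grayscale equals the given array."""
    return np.repeat(np.asarray(gray, np.uint8)[:, :, None], 3, axis=2)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_glcm_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    gray = rng.integers(0, 256, size=(8, 8))
    mask = rng.random((8, 8)) < 0.8
    mask[0, 0] = True  # keep nonempty
    out = texture_features(_gray_image(gray), mask)
    oracle = _glcm_oracle(gray, mask)
    for name in TEXTURE_FEATURES:
        assert out[name] == pytest.approx(oracle[name], rel=1e-12, abs=1e-12)


def test_glcm_checkerboard_patch_oracle():
    gray = np.tile([[0, 255], [255, 0]], (2, 2))
    mask = np.ones((4, 4), dtype=bool)
    out = texture_features(_gray_image(gray), mask)
    oracle = _glcm_oracle(gray, mask)
    for name in TEXTURE_FEATURES:
        assert out[name] == pytest.approx(oracle[name], rel=1e-12, abs=1e-12)


def test_glcm_uniform_region_degenerate():
    img = np.full((5, 5, 3), 77, dtype=np.uint8)
    out = texture_features(img, np.ones((5, 5), bool))
    assert out["contrast"] == 0.0
    assert out["dissimilarity"] == 0.0
    assert out["homogeneity"] == pytest.approx(1.0)
    assert out["ASM"] == pytest.approx(1.0)
    assert out["energy"] == pytest.approx(1.0)
    assert out["correlation"] == 1.0  # convention for a single grey level


def test_energy_squared_equals_asm(rendered_sample):
    out = texture_features(rendered_sample.image, rendered_sample.truth_mask)
    assert out["energy"] ** 2 == pytest.approx(out["ASM"], rel=1e-12)


def test_glcm_excludes_background_pixels():
    """A bright border outside the mask must not affect the features."""
    gray = np.full((6, 6), 100)
    mask = np.zeros((6, 6), dtype=bool)
    mask[2:5, 2:5] = True
    a = texture_features(_gray_image(gray), mask)
    gray2 = gray.copy()
    gray2[~mask] = 250
    b = texture_features(_gray_image(gray2), mask)
    assert a == b


# -------------------------------------------------------------- geometry


def test_square_geometry_closed_forms():
    mask = np.zeros((60, 60), dtype=bool)
    s = 40
    mask[10:10 + s, 10:10 + s] = True
    out = geometry_features(mask)
    assert out["contour_area"] == s * s
    assert out["w"] == s and out["h"] == s
    assert out["aspect_ratio"] == 1.0
    assert out["extent"] == 1.0
    assert out["solidity"] == pytest.approx(1.0, rel=0.01)
    assert out["equivalent_diameter"] == pytest.approx(s * np.sqrt(4 / np.pi),
                                                       rel=1e-9)


def test_disc_geometry_within_two_percent(disc_mask):
    out = geometry_features(disc_mask)
    assert out["r"] == pytest.approx(50, rel=0.02)
    assert out["equivalent_diameter"] == pytest.approx(100, rel=0.02)
    assert out["solidity"] == pytest.approx(1.0, rel=0.02)
    assert out["MA"] == pytest.approx(100, rel=0.02)
    assert out["ma"] == pytest.approx(100, rel=0.02)


def test_hull_bounds_any_mask(rendered_sample):
    out = geometry_features(rendered_sample.truth_mask)
    assert out["solidity"] <= 1.0
    assert out["hull_area"] >= out["contour_area"]
    assert out["_w"] >= out["_h"]


def test_mm_scale_applies_to_areas_and_lengths(disc_mask):
    px = geometry_features(disc_mask)
    mm = geometry_features(disc_mask, CalibrationScale(mm_per_px=0.5))
    assert mm["contour_area"] == pytest.approx(px["contour_area"] * 0.25)
    assert mm["r"] == pytest.approx(px["r"] * 0.5)
    assert mm["solidity"] == pytest.approx(px["solidity"])


def test_multiple_components_uses_largest_with_warning(disc_mask):
    mask = disc_mask.copy()
    mask[2:5, 2:5] = True
    with pytest.warns(UserWarning, match="largest"):
        out = geometry_features(mask)
    assert out["contour_area"] == disc_mask.sum()


# ------------------------------------------------------------ extraction


def test_extract_all_has_65_features_in_order(rendered_sample):
    out = extract_all(rendered_sample.image, rendered_sample.truth_mask)
    assert list(out) == FEATURE_NAMES
    assert all(np.isfinite(v) for v in out.values())


def test_extract_deterministic(rendered_sample):
    a = extract_all(rendered_sample.image, rendered_sample.truth_mask)
    b = extract_all(rendered_sample.image, rendered_sample.truth_mask)
    assert a == b


def test_translation_invariance(rendered_sample):
    img, mask = rendered_sample.image, rendered_sample.truth_mask
    a = extract_all(img, mask)
    img2 = np.roll(img, (7, 11), axis=(0, 1))
    mask2 = np.roll(mask, (7, 11), axis=(0, 1))
    b = extract_all(img2, mask2)
    for name in FEATURE_NAMES:
        assert b[name] == pytest.approx(a[name], rel=1e-6, abs=1e-9), name


def test_rotation90_invariant_subset(rendered_sample):
    img, mask = rendered_sample.image, rendered_sample.truth_mask
    a = extract_all(img, mask)
    b = extract_all(np.rot90(img), np.rot90(mask))
    for name in ["contour_area", "hull_area", "r", "equivalent_diameter",
                 "solidity"]:
        assert b[name] == pytest.approx(a[name], rel=0.01), name


def test_phenotype_extractor_transformer(rendered_sample):
    ext = PhenotypeExtractor()
    df = ext.fit().transform([(rendered_sample.image, rendered_sample.truth_mask)])
    assert df.shape == (1, 65)
    assert list(df.columns) == FEATURE_NAMES
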