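"""Phenotypic feature extraction: 65 color, texture and geometry features.

For a segmented top-view plant image the extractor computes, in a fixed
order:

* 45 color statistics — mean, standard deviation (population), median,
  range and coefficient of variation for each of the nine channels
  R, G, B, L, a, b, H, S, V, over plant pixels only;
* 6 grey-level co-occurrence (Haralick) texture features — contrast,
  dissimilarity, homogeneity, energy, correlation and angular second
  moment (ASM) — from a symmetric, normalized co-occurrence matrix
  averaged over the four canonical directions at distance 1, with
  background pixels excluded from the pair counts;
* 14 contour-geometry features of the plant region — contour area,
  perimeter, bounding-box width/height, convex-hull area, minimum-area
  rotated rectangle sides, ellipse axes, minimum enclosing circle
  radius, equivalent diameter, aspect ratio, extent and solidity.

Channel conventions follow the common 8-bit image-toolchain scaling:
H on the half-degree scale [0, 180), S and V in [0, 255], L in
[0, 255], a and b offset by +128.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from shapely import MultiPoint, minimum_bounding_radius
from skimage.color import rgb2hsv, rgb2lab
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import label, regionprops
from sklearn.base import BaseEstimator, TransformerMixin

from .segmentation import to_grayscale

__all__ = [
    "FEATURE_NAMES",
    "GLCMParams",
    "CalibrationScale",
    "color_features",
    "texture_features",
    "geometry_features",
    "extract_all",
    "extract_table",
    "PhenotypeExtractor",
]

_CHANNELS = ["R", "G", "B", "L", "a", "b", "H", "S", "V"]
_STATS = ["mean", "std", "median", "range", "cv"]

COLOR_FEATURES = [f"{ch}_{st}" for ch in _CHANNELS for st in _STATS]
TEXTURE_FEATURES = ["contrast", "dissimilarity", "homogeneity", "energy",
                    "correlation", "ASM"]
GEOMETRY_FEATURES = ["contour_area", "perimeter", "w", "h", "hull_area",
                     "_w", "_h", "MA", "ma", "r", "equivalent_diameter",
                     "aspect_ratio", "extent", "solidity"]

#: The 65 feature names in canonical order (1-45 color, 46-51 texture,
#: 52-65 morphology).
FEATURE_NAMES = COLOR_FEATURES + TEXTURE_FEATURES + GEOMETRY_FEATURES


@dataclass
class GLCMParams:
    """Grey-level co-occurrence configuration (canonical Haralick setup)."""

    distance: int = 1
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    levels: int = 256
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not 2 <= self.levels <= 256:
            raise ValueError("levels must be in [2, 256]")


@dataclass
class CalibrationScale:
    """Image calibration: millimetres per pixel (1.0 = report pixel units)."""

    mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def _channel_stack(image: np.ndarray) -> np.ndarray:
    """(H, W, 9) float stack of R,G,B,L,a,b,H,S,V in 8-bit-style scales."""
    image = np.asarray(image)
    rgb01 = image.astype(np.float64) / 255.0
    lab = rgb2lab(rgb01)
    lab8 = np.stack(
        [lab[..., 0] * 255.0 / 100.0, lab[..., 1] + 128.0, lab[..., 2] + 128.0],
        axis=-1,
    )
    hsv = rgb2hsv(rgb01)
    hsv8 = np.stack(
        [hsv[..., 0] * 180.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0], axis=-1
    )
    return np.concatenate([image.astype(np.float64), lab8, hsv8], axis=-1)


def color_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """The 45 per-channel color statistics over plant pixels."""
    mask = _check_mask(mask)
    stack = _channel_stack(image)
    out: dict[str, float] = {}
    for i, ch in enumerate(_CHANNELS):
        vals = stack[..., i][mask]
        mean = float(vals.mean())
        std = float(vals.std())  # population std
        if mean == 0.0 and std > 0.0:
            warnings.warn(f"channel {ch}: zero mean, CV set to 0")
        out[f"{ch}_mean"] = mean
        out[f"{ch}_std"] = std
        out[f"{ch}_median"] = float(np.median(vals))
        out[f"{ch}_range"] = float(vals.max() - vals.min())
        out[f"{ch}_cv"] = std / mean if mean != 0.0 else 0.0
    return out


def _masked_glcm(gray: np.ndarray, mask: np.ndarray, params: GLCMParams) -> np.ndarray:
    """Angle-averaged normalized co-occurrence matrix over plant pixels.

    Background pixels are mapped to a sentinel grey level; pairs
    touching the sentinel are dropped before normalization, so only
    pairs of plant pixels contribute.
    """
    levels = params.levels
    # requantize 0..255 grayscale onto `levels` bins
    q = np.floor(gray * levels / 256.0).astype(np.int64)
    q = np.clip(q, 0, levels - 1)
    q[~mask] = levels  # sentinel
    angles = np.deg2rad(params.angles_deg)
    counts = graycomatrix(
        q,
        distances=[params.distance],
        angles=angles,
        levels=levels + 1,
        symmetric=params.symmetric,
        normed=False,
    ).astype(np.float64)
    counts = counts[:levels, :levels, 0, :]  # drop sentinel row/col
    mats = []
    for k in range(counts.shape[-1]):
        c = counts[..., k]
        s = c.sum()
        if s > 0:
            mats.append(c / s if params.normalized else c)
    if not mats:
        raise ValueError("mask too sparse: no valid co-occurrence pairs")
    return np.mean(mats, axis=0)


def texture_features(
    image: np.ndarray, mask: np.ndarray, params: GLCMParams | None = None
) -> dict[str, float]:
    """The 6 Haralick features from the angle-averaged co-occurrence matrix.

    With a single occupied grey level the matrix is degenerate and the
    correlation is 1 by convention.
    """
    params = params or GLCMParams()
    mask = _check_mask(mask)
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    if rows.size < 2 and cols.size < 2:
        raise ValueError("mask bounding box must be at least 2 pixels wide or tall")
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    gray = to_grayscale(image)[sl]
    p = _masked_glcm(gray, mask[sl], params)
    p4 = p[:, :, None, None]
    out = {}
    for prop in TEXTURE_FEATURES:
        out[prop] = float(graycoprops(p4, prop)[0, 0])
    return out


def _rect_sides(points: np.ndarray) -> tuple[float, float]:
    """Side lengths (long, short) of the minimum-area rotated rectangle."""
    rect = MultiPoint(points).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (collinear points)
        length = rect.length if rect.geom_type == "LineString" else 0.0
        return float(length), 0.0
    xs, ys = rect.exterior.coords.xy
    s1 = float(np.hypot(xs[1] - xs[0], ys[1] - ys[0]))
    s2 = float(np.hypot(xs[2] - xs[1], ys[2] - ys[1]))
    return max(s1, s2), min(s1, s2)


def geometry_features(
    mask: np.ndarray, scale: CalibrationScale | None = None
) -> dict[str, float]:
    """The 14 contour-geometry features of the largest plant region.

    Areas are scaled by ``mm_per_px ** 2`` and lengths by ``mm_per_px``;
    with the default calibration of 1 everything is in pixel units.
    If several components are present the largest is taken as the plant
    and the rest are ignored with a warning.
    """
    scale = scale or CalibrationScale()
    mask = _check_mask(mask)
    labels = label(mask, connectivity=2)
    regions = sorted(regionprops(labels), key=lambda reg: reg.area, reverse=True)
    if len(regions) > 1:
        warnings.warn(f"{len(regions)} components in mask; using the largest")
    region = regions[0]

    s = scale.mm_per_px
    area = float(region.area)
    perimeter = float(region.perimeter)
    minr, minc, maxr, maxc = region.bbox
    w = float(maxc - minc)
    h = float(maxr - minr)
    hull_area = float(region.area_convex)

    coords = region.coords.astype(np.float64)
    if len(coords) >= 3:
        try:
            hull_pts = coords[ConvexHull(coords).vertices]
        except Exception:  # collinear coords
            hull_pts = coords
    else:
        hull_pts = coords
    rect_long, rect_short = _rect_sides(hull_pts)
    radius = float(minimum_bounding_radius(MultiPoint(hull_pts)))

    ma_major = float(region.axis_major_length)
    ma_minor = float(region.axis_minor_length)
    if len(coords) < 5 or not np.isfinite(ma_major) or ma_major == 0.0:
        warnings.warn("too few points for an ellipse fit; using rectangle sides")
        ma_major, ma_minor = rect_long, rect_short

    eq_diam = float(np.sqrt(4.0 * area / np.pi))
    return {
        "contour_area": area * s**2,
        "perimeter": perimeter * s,
        "w": w * s,
        "h": h * s,
        "hull_area": hull_area * s**2,
        "_w": rect_long * s,
        "_h": rect_short * s,
        "MA": ma_major * s,
        "ma": ma_minor * s,
        "r": radius * s,
        "equivalent_diameter": eq_diam * s,
        "aspect_ratio": w / h,
        "extent": area / (w * h),
        "solidity": area / hull_area if hull_area > 0 else 0.0,
    }


def extract_all(
    image: np.ndarray,
    mask: np.ndarray,
    glcm: GLCMParams | None = None,
    scale: CalibrationScale | None = None,
) -> dict[str, float]:
    """All 65 features in canonical order for one (image, mask) pair."""
    out: dict[str, float] = {}
    out.update(color_features(image, mask))
    out.update(texture_features(image, mask, glcm))
    out.update(geometry_features(mask, scale))
    assert list(out) == FEATURE_NAMES
    return out


def extract_table(
    images,
    masks,
    sample_ids=None,
    glcm: GLCMParams | None = None,
    scale: CalibrationScale | None = None,
):
    """Feature table (one row per sample, 65 columns) for paired images/masks."""
    import pandas as pd

    rows = [extract_all(img, msk, glcm, scale) for img, msk in zip(images, masks)]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    if sample_ids is not None:
        df.insert(0, "sample_id", list(sample_ids))
    return df


class PhenotypeExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping (image, mask) pairs to 65-feature rows.

    ``transform`` accepts an iterable of ``(image, mask)`` pairs and
    returns a DataFrame with one column per feature.
    """

    def __init__(
        self,
        glcm_distance: int = 1,
        glcm_levels: int = 256,
        mm_per_px: float = 1.0,
    ):
        self.glcm_distance = glcm_distance
        self.glcm_levels = glcm_levels
        self.mm_per_px = mm_per_px

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        glcm = GLCMParams(distance=self.glcm_distance, levels=self.glcm_levels)
        scale = CalibrationScale(mm_per_px=self.mm_per_px)
        images, masks = zip(*X)
        return extract_table(images, masks, glcm=glcm, scale=scale)
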