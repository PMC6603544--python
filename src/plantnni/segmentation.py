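"""Top-view plant segmentation by excess-green banding and brightness rejection.

The segmenter reproduces a classic visible-light pipeline for potted
plants photographed against a near-white background:

1. excess green index ExG = 2G - R - B, kept inside a band
   (defaults 40..200, inclusive);
2. grayscale conversion, with high-brightness pixels (>= 240 by
   default) rejected;
3. intersection of the two masks;
4. morphological opening with a small square element;
5. removal of connected components smaller than one tenth of the mask
   area, then filling of background holes smaller than one twentieth
   of the mask area (restoring leaf veins lost to the ExG band).

All steps are deterministic.  Boundary conventions (inclusive ExG band,
strict brightness cut, fractional areas recomputed between steps) are
pinned here and in the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology
from skimage.measure import label
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NoPlantDetected",
    "SegmentationParams",
    "compute_exg",
    "exg_mask",
    "gray_mask",
    "clean_mask",
    "segment_plant",
    "PlantSegmenter",
]

# ITU-R BT.601 luma weights
_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


class NoPlantDetected(ValueError):
    """Raised when segmentation produces an empty mask ("no plant detected")."""


@dataclass
class SegmentationParams:
    """Tunable thresholds of the segmentation flow.

    exg_min, exg_max : inclusive band on the excess green index.
    gray_max : pixels with grayscale >= gray_max are rejected (strict
        "member" condition gray < gray_max).
    open_kernel_px : side of the square structuring element for opening.
    min_object_frac : components smaller than this fraction of the
        current mask area are removed.
    max_hole_frac : background holes smaller than this fraction of the
        current mask area are filled.
    """

    exg_min: int = 40
    exg_max: int = 200
    gray_max: int = 240
    open_kernel_px: int = 3
    min_object_frac: float = 1 / 10
    max_hole_frac: float = 1 / 20

    def __post_init__(self) -> None:
        if not 0 <= self.exg_min <= self.exg_max:
            raise ValueError("require 0 <= exg_min <= exg_max")
        if not 0 < self.gray_max <= 255:
            raise ValueError("gray_max must be in (0, 255]")
        for name in ("min_object_frac", "max_hole_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.open_kernel_px < 1:
            raise ValueError("open_kernel_px must be >= 1")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return image


def compute_exg(image: np.ndarray) -> np.ndarray:
    """Excess green index 2G - R - B in signed arithmetic (range -510..510)."""
    image = _check_image(image).astype(np.int32)
    return 2 * image[..., 1] - image[..., 0] - image[..., 2]


def exg_mask(exg: np.ndarray, exg_min: int = 40, exg_max: int = 200) -> np.ndarray:
    """Membership in the inclusive ExG band [exg_min, exg_max]."""
    if exg_min > exg_max:
        raise ValueError("exg_min must not exceed exg_max")
    exg = np.asarray(exg)
    return (exg >= exg_min) & (exg <= exg_max)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rounded BT.601 grayscale of an 8-bit RGB image."""
    image = _check_image(image)
    return np.rint(image.astype(np.float64) @ _GRAY_WEIGHTS)


def gray_mask(image: np.ndarray, gray_max: int = 240) -> np.ndarray:
    """Mask of pixels below the brightness cut (gray < gray_max, strict)."""
    return to_grayscale(image) < gray_max


def clean_mask(mask: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Morphological opening, small-object removal and small-hole filling.

    The fractional size thresholds refer to the total foreground area
    of the mask at the moment each filter runs (recomputed between
    steps).  Objects use 8-connectivity, holes 4-connectivity; a hole
    is a background component not touching the image border.

    Raises :class:`NoPlantDetected` if the mask is empty at any stage.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoPlantDetected("no plant detected: empty input mask")

    k = params.open_kernel_px
    opened = morphology.opening(mask, footprint=np.ones((k, k), dtype=bool))
    if not opened.any():
        raise NoPlantDetected("no plant detected: mask empty after opening")

    # remove objects smaller than min_object_frac of the current mask area
    total = opened.sum()
    labels = label(opened, connectivity=2)
    keep = np.zeros_like(opened)
    for lbl in range(1, labels.max() + 1):
        comp = labels == lbl
        if comp.sum() >= params.min_object_frac * total:
            keep |= comp
    if not keep.any():
        raise NoPlantDetected("no plant detected: mask empty after object removal")

    # fill background holes smaller than max_hole_frac of the current area
    total = keep.sum()
    bg = label(~keep, connectivity=1)
    border_labels = np.unique(
        np.concatenate([bg[0, :], bg[-1, :], bg[:, 0], bg[:, -1]])
    )
    filled = keep.copy()
    for lbl in range(1, bg.max() + 1):
        if lbl in border_labels:
            continue
        hole = bg == lbl
        if hole.sum() < params.max_hole_frac * total:
            filled |= hole
    return filled


def segment_plant(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Full segmentation flow: ExG band ∧ brightness cut, then cleaning."""
    params = params or SegmentationParams()
    raw = exg_mask(compute_exg(image), params.exg_min, params.exg_max) & gray_mask(
        image, params.gray_max
    )
    if not raw.any():
        raise NoPlantDetected("no plant detected")
    return clean_mask(raw, params)


class PlantSegmenter(BaseEstimator, TransformerMixin):
    """Stateless transformer applying :func:`segment_plant` to each image.

    Parameters mirror :class:`SegmentationParams`.  ``fit`` is a no-op
    (there is nothing to learn); ``transform`` maps a sequence of RGB
    images to a list of boolean masks.
    """

    def __init__(
        self,
        exg_min: int = 40,
        exg_max: int = 200,
        gray_max: int = 240,
        open_kernel_px: int = 3,
        min_object_frac: float = 1 / 10,
        max_hole_frac: float = 1 / 20,
    ):
        self.exg_min = exg_min
        self.exg_max = exg_max
        self.gray_max = gray_max
        self.open_kernel_px = open_kernel_px
        self.min_object_frac = min_object_frac
        self.max_hole_frac = max_hole_frac

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            exg_min=self.exg_min,
            exg_max=self.exg_max,
            gray_max=self.gray_max,
            open_kernel_px=self.open_kernel_px,
            min_object_frac=self.min_object_frac,
            max_hole_frac=self.max_hole_frac,
        )

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> list[np.ndarray]:
        params = self._params()
        return [segment_plant(img, params) for img in X]
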