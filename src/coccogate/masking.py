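"""Mask construction for single-object cross-polarised images.

Three mask types drive the morphometry of birefringent particles:

* the **object (tight) mask**, a segmentation that hugs the particle and is
  the basis for diameter, circularity and aspect-ratio measurements;
* the **peak mask**, which marks regions of locally high intensity (bright
  detail) inside the tight mask;
* the **range mask**, which keeps only peak components whose physical area
  falls inside a closed interval (default 0.56-555.56 um^2).

The composition peak -> range is the *combined peak-range mask* whose
8-connected components are the "bright spots" counted by the gating
protocol (a well-preserved face-on coccolith shows exactly 4, the
pseudo-extinction cross; a coccosphere shows 5 or more).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as sk_label
from skimage.morphology import disk, white_tophat

from .errors import InvalidInputError, InvalidParameterError

MASK_OBJECT_TIGHT = "object_tight"
MASK_PEAK = "peak"
MASK_RANGE = "range"
MASK_PEAK_RANGE = "peak_range"


@dataclass(frozen=True)
class ObjectImage:
    """One detected object's polarised-channel pixel grid.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (8-bit scale by convention,
        stored as float).
    pixel_area
        Physical area of one pixel in um^2 (0.33 at 60X magnification).
    object_id
        Stable identifier used to join images, truth and feature tables.
    channel
        Acquisition channel label; the polarised channel by default.
    """

    pixels: np.ndarray
    pixel_area: float = 0.33
    object_id: str = "obj"
    channel: str = "polarised"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError("ObjectImage.pixels must be a non-empty 2-D grid")
        if not self.pixel_area > 0:
            raise InvalidParameterError("pixel_area must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Pixel-aligned boolean region over an :class:`ObjectImage` grid."""

    pixels: np.ndarray
    kind: str = MASK_OBJECT_TIGHT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError("BinaryMask.pixels must be a non-empty 2-D grid")
        object.__setattr__(self, "pixels", px)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass(frozen=True)
class MaskConfig:
    """Tunable parameters of the mask chain.

    spot_to_bg_ratio
        Peak threshold expressed as a multiple of the background level
        (median intensity outside the tight mask).
    detail_radius_um
        Radius of the structuring element for top-hat peak detection;
        bright detail larger than this scale is treated as object body,
        not as a spot.
    spot_area_range
        Closed physical-area interval (um^2) a peak component must fall in
        to count as a bright spot.
    contrast_min
        Minimum foreground/background median-intensity ratio for the tight
        mask to be considered a real detection (guards against segmenting
        sensor noise on empty frames).
    closing_radius
        Radius (px) of the morphological closing applied to the tight mask.
    """

    spot_to_bg_ratio: float = 3.0
    detail_radius_um: float = 1.7
    spot_area_range: tuple[float, float] = (0.56, 555.56)
    contrast_min: float = 3.0
    closing_radius: int = 2


def _empty_like(image: ObjectImage, kind: str) -> BinaryMask:
    return BinaryMask(np.zeros(image.shape, dtype=bool), kind)


def object_tight_mask(
    image: ObjectImage,
    *,
    contrast_min: float = 3.0,
    closing_radius: int = 2,
) -> BinaryMask:
    """Segment the object from background; keep the largest component.

    The background-separation threshold is the lower of Otsu's and the
    triangle threshold: Otsu alone overshoots on extinction-cross objects
    whose histogram is dominated by dark pixels, while the triangle
    threshold tracks the background foot. A closing bridges the dark
    extinction arms of calcite crosses, holes are filled and only the
    largest 8-connected component is retained, so isolated speckle never
    inflates the object. If the segmented foreground does not stand out
    from the background (flat or noise-only frames) the mask is empty,
    which the feature extractor reports as a non-detection. All decision
    rules are ratios of intensities, so the mask is invariant to rescaling
    the image by any positive constant.
    """
    img = image.pixels
    if not np.isfinite(img).all():
        raise InvalidInputError("image contains non-finite intensities")
    if img.max() <= 0 or np.ptp(img) == 0:
        return _empty_like(image, MASK_OBJECT_TIGHT)
    thresh = min(threshold_otsu(img), threshold_triangle(img))
    # relative floor keeps the upper tail of background noise out of the
    # foreground when the triangle threshold lands inside the noise band
    med = float(np.median(img))
    thresh = max(thresh, med + 0.05 * (float(img.max()) - med))
    fg = img > thresh
    if not fg.any() or fg.all():
        return _empty_like(image, MASK_OBJECT_TIGHT)
    bg_level = float(np.median(img[~fg]))
    fg_level = float(np.median(img[fg]))
    if bg_level > 0 and fg_level < contrast_min * bg_level:
        # foreground does not stand out from background: no detection
        return _empty_like(image, MASK_OBJECT_TIGHT)
    if closing_radius > 0:
        # dilate -> fill -> erode: a closing with hole-filling in between,
        # so the dark extinction arms and core of a calcite cross are
        # absorbed into the plate outline instead of splitting it
        selem = disk(closing_radius)
        fg = ndi.binary_dilation(fg, structure=selem)
        fg = ndi.binary_fill_holes(fg)
        fg = ndi.binary_erosion(fg, structure=selem, border_value=1)
    else:
        fg = ndi.binary_fill_holes(fg)
    labels = sk_label(fg, connectivity=2)
    if labels.max() == 0:
        return _empty_like(image, MASK_OBJECT_TIGHT)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(counts.argmax())
    return BinaryMask(labels == keep, MASK_OBJECT_TIGHT)


def peak_mask(
    image: ObjectImage,
    within: BinaryMask,
    spot_to_bg_ratio: float = 3.0,
    *,
    detail_radius_um: float = 1.7,
) -> BinaryMask:
    """Mark bright-detail regions inside the tight mask.

    Local prominence is measured with a white top-hat (image minus its
    grey opening under a disk of ``detail_radius_um``), which suppresses
    the object's own body and leaves only bright detail smaller than the
    disk. A pixel is a peak pixel when its prominence is at least
    ``spot_to_bg_ratio`` times the background level (median intensity
    outside ``within``); the comparison is inclusive.
    """
    if within.kind != MASK_OBJECT_TIGHT:
        raise InvalidParameterError(
            f"peak_mask expects an object_tight mask, got kind={within.kind!r}"
        )
    if not spot_to_bg_ratio > 1:
        raise InvalidParameterError("spot_to_bg_ratio must be > 1")
    if within.pixels.shape != image.shape:
        raise InvalidInputError("mask shape does not match image shape")
    if within.is_empty():
        return _empty_like(image, MASK_PEAK)

    img = image.pixels
    radius_px = max(2, math.ceil(detail_radius_um / math.sqrt(image.pixel_area)))
    tophat = white_tophat(img, disk(radius_px))

    outside = ~within.pixels
    bg_level = float(np.median(img[outside])) if outside.any() else 0.0
    thresh = spot_to_bg_ratio * bg_level
    peaks = within.pixels & (tophat >= thresh) & (tophat > 0)
    return BinaryMask(peaks, MASK_PEAK)


def range_mask(
    mask: BinaryMask,
    min_area_um2: float,
    max_area_um2: float,
    pixel_area: float,
) -> BinaryMask:
    """Keep connected components whose physical area lies in a closed interval.

    Component areas are ``n_pixels * pixel_area`` (um^2); 8-connectivity.
    """
    if min_area_um2 < 0 or max_area_um2 < 0:
        raise InvalidParameterError("area bounds must be non-negative")
    if min_area_um2 > max_area_um2:
        raise InvalidParameterError("min_area_um2 must be <= max_area_um2")
    if not pixel_area > 0:
        raise InvalidParameterError("pixel_area must be > 0")
    out_kind = MASK_PEAK_RANGE if mask.kind == MASK_PEAK else MASK_RANGE
    labels = sk_label(mask.pixels, connectivity=2)
    if labels.max() == 0:
        return BinaryMask(np.zeros_like(mask.pixels), out_kind)
    areas = np.bincount(labels.ravel()).astype(float) * pixel_area
    areas[0] = np.nan
    ok = (areas >= min_area_um2) & (areas <= max_area_um2)
    keep = ok[labels]
    keep[labels == 0] = False
    return BinaryMask(keep, out_kind)


def combined_peak_range_mask(
    image: ObjectImage,
    config: MaskConfig | None = None,
    *,
    tight: BinaryMask | None = None,
) -> BinaryMask:
    """Compose tight -> peak -> range masks; components are bright spots.

    ``tight`` may be supplied to reuse a precomputed object mask.
    """
    cfg = config or MaskConfig()
    if tight is None:
        tight = object_tight_mask(
            image, contrast_min=cfg.contrast_min, closing_radius=cfg.closing_radius
        )
    peaks = peak_mask(
        image,
        tight,
        cfg.spot_to_bg_ratio,
        detail_radius_um=cfg.detail_radius_um,
    )
    lo, hi = cfg.spot_area_range
    return range_mask(peaks, lo, hi, image.pixel_area)
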