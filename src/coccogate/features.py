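"""Per-object morphometric features used by the gating protocol.

Five features drive the decision protocol: equal-area diameter,
circularity (mean boundary distance from the centroid divided by its
standard deviation - the imaging-flow-cytometry convention, not the
isoperimetric ratio), bright-spot count from the combined peak-range mask,
Gradient RMS (a sharpness score used to reject out-of-focus frames) and
aspect ratio (minor/major axis of the tight mask, low for doublets).
``max_intensity`` of the raw frame supports the birefringence pre-filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import sobel
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import FeatureUndefinedError, InvalidInputError
from .masking import (
    BinaryMask,
    MaskConfig,
    ObjectImage,
    combined_peak_range_mask,
    object_tight_mask,
)

#: Sentinel returned by :func:`circularity` for a perfectly circular boundary
#: (zero radial variation); compares greater than any finite gate threshold.
CIRCULARITY_INFINITE = math.inf

FEATURE_COLUMNS = [
    "object_id",
    "area_um2",
    "diameter_um",
    "circularity",
    "spot_count",
    "gradient_rms",
    "aspect_ratio",
    "max_intensity",
    "detected",
]


@dataclass(frozen=True)
class FeatureRecord:
    """The per-object feature vector consumed by the gates."""

    object_id: str
    area_um2: float
    diameter_um: float
    circularity: float
    spot_count: int
    gradient_rms: float
    aspect_ratio: float
    max_intensity: float
    detected: bool

    def to_dict(self) -> dict:
        return asdict(self)


def equal_area_diameter(mask: BinaryMask, pixel_area: float) -> float:
    """Diameter (um) of the circle with the same area as the mask."""
    n = mask.n_pixels
    if n == 0:
        raise FeatureUndefinedError("diameter undefined for an empty mask")
    if not pixel_area > 0:
        raise InvalidInputError("pixel_area must be > 0")
    return 2.0 * math.sqrt(n * pixel_area / math.pi)


def boundary_pixels(mask: BinaryMask) -> np.ndarray:
    """(row, col) coordinates of mask pixels with >=1 non-mask 4-neighbour.

    Pixels on the array border count as boundary (the outside is background).
    """
    px = mask.pixels
    interior = ndi.binary_erosion(
        px, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(px & ~interior)


def circularity(mask: BinaryMask) -> float:
    """Mean distance of boundary pixels from the mask centroid / its SD.

    Distances are Euclidean, the centroid is of the full mask, and the
    standard deviation is the population SD. A perfect circle would have
    zero variation; that degenerate case returns ``CIRCULARITY_INFINITE``
    so that >= gates always pass. High values (>= 10 by the default gate)
    indicate quasi-circular objects such as coccospheres.
    """
    bnd = boundary_pixels(mask)
    if len(bnd) < 8:
        raise FeatureUndefinedError(
            f"circularity needs >= 8 boundary pixels, got {len(bnd)}"
        )
    centroid = np.argwhere(mask.pixels).mean(axis=0)
    dists = np.hypot(*(bnd - centroid).T)
    sd = float(dists.std())  # population SD
    if sd == 0:
        return CIRCULARITY_INFINITE
    return float(dists.mean()) / sd


def spot_count(peak_range: BinaryMask) -> int:
    """Number of 8-connected components of the combined peak-range mask."""
    return int(sk_label(peak_range.pixels, connectivity=2).max())


#: Gradient RMS scale divisor: the raw RMS Sobel magnitude of a 0-255
#: image is divided by this so that the conventional focus threshold (15)
#: separates the synthetic generator's in-focus and defocused classes.
GRADIENT_RMS_SCALE = 2.5


def gradient_rms(image: ObjectImage, mask: BinaryMask) -> float:
    """Sharpness score: RMS Sobel gradient magnitude over the mask's bbox.

    The image is min-max rescaled to 0-255 first so the score depends on
    contrast structure, not absolute exposure, then divided by
    ``GRADIENT_RMS_SCALE``. The default focus gate (> 15) is calibrated on
    the synthetic generator; the instrument-software scale is proprietary,
    so for real exports the threshold should be re-checked.
    """
    if mask.is_empty():
        raise FeatureUndefinedError("gradient_rms undefined for an empty mask")
    if mask.pixels.shape != image.shape:
        raise InvalidInputError("mask shape does not match image shape")
    img = image.pixels
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return 0.0
    rescaled = (img - lo) * (255.0 / (hi - lo))
    grad = sobel(rescaled)
    rows = np.any(mask.pixels, axis=1).nonzero()[0]
    cols = np.any(mask.pixels, axis=0).nonzero()[0]
    box = grad[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return float(np.sqrt(np.mean(box**2)) / GRADIENT_RMS_SCALE)


def aspect_ratio(mask: BinaryMask) -> float:
    """Minor/major axis ratio from the mask's second central moments.

    In (0, 1]; near 1 for single round objects, ~0.5 for tangent-disk
    doublets. Degenerate (collinear) masks return 0.0 rather than raising.
    """
    n = mask.n_pixels
    if n < 2:
        raise FeatureUndefinedError("aspect_ratio needs a mask with >= 2 pixels")
    props = regionprops(mask.pixels.astype(np.uint8))[0]
    major = props.axis_major_length
    if major == 0:
        return 0.0
    return min(props.axis_minor_length / major, 1.0)


def extract_features(
    image: ObjectImage, config: MaskConfig | None = None
) -> FeatureRecord:
    """Run the full mask chain on one object and assemble its feature record.

    Objects whose tight mask is empty (nothing above background) yield a
    record flagged ``detected=False`` with NaN morphometrics; downstream
    gates treat them as non-birefringent.
    """
    cfg = config or MaskConfig()
    tight = object_tight_mask(
        image, contrast_min=cfg.contrast_min, closing_radius=cfg.closing_radius
    )
    max_intensity = float(image.pixels.max())
    if tight.is_empty():
        return FeatureRecord(
            object_id=image.object_id,
            area_um2=float("nan"),
            diameter_um=float("nan"),
            circularity=float("nan"),
            spot_count=0,
            gradient_rms=float("nan"),
            aspect_ratio=float("nan"),
            max_intensity=max_intensity,
            detected=False,
        )
    area = tight.n_pixels * image.pixel_area
    diam = equal_area_diameter(tight, image.pixel_area)
    try:
        circ = circularity(tight)
    except FeatureUndefinedError:
        circ = float("nan")
    try:
        ar = aspect_ratio(tight)
    except FeatureUndefinedError:
        ar = float("nan")
    spots = spot_count(combined_peak_range_mask(image, cfg, tight=tight))
    grms = gradient_rms(image, tight)
    return FeatureRecord(
        object_id=image.object_id,
        area_um2=area,
        diameter_um=diam,
        circularity=circ,
        spot_count=spots,
        gradient_rms=grms,
        aspect_ratio=ar,
        max_intensity=max_intensity,
        detected=True,
    )


def extract_feature_table(
    images: list[ObjectImage], config: MaskConfig | None = None
) -> pd.DataFrame:
    """Feature records for a gallery, one row per object, order preserved."""
    records = [extract_features(img, config).to_dict() for img in images]
    if not records:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.DataFrame.from_records(records)[FEATURE_COLUMNS]
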