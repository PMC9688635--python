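"""Background estimation and dark-object segmentation for bright-field RGB.

Objects of interest — cells, beads, conjugate clusters — are darker than the
bright background in every color band, so the foreground criterion is a
minimum per-band deficit from the estimated background.  Touching or
overlapping objects are reported as one region, matching how conjugate
clusters are treated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ConfigurationError, FieldTooCrowdedError

#: Minimum per-band deficit for a pixel to count as foreground.  Below the
#: weakest object-class deficit (15, the unstained cell) so even faint cells
#: are retained.
DEFAULT_MIN_DEFICIT = 10.0

#: Minimum Otsu class separation (intensity units) for the frame to be
#: treated as containing objects at all; below this the whole frame is
#: background and Otsu would merely split the noise.
_MIN_SEPARATION = 10.0


@dataclass(frozen=True)
class BackgroundEstimate:
    mean_rgb: tuple[float, float, float]
    sd_rgb: tuple[float, float, float]
    method: str = "otsu-luminance"

    @property
    def mean(self) -> np.ndarray:
        return np.asarray(self.mean_rgb, dtype=float)


@dataclass(frozen=True)
class SegmentedObject:
    """A labeled connected region with its area and per-band interior mean."""

    label: int
    area_px: int
    centroid: tuple[float, float]
    mean_rgb: tuple[float, float, float]
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open


def _check_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ConfigurationError(f"expected an RGB image, got shape {image.shape}")
    return image


def default_min_object_area(pixel_scale: float) -> float:
    """Area (px) of a 2 um disk at the given scale — the size floor."""
    r = 1.0 / pixel_scale
    return max(np.pi * r * r, 1.0)


def estimate_background(image: np.ndarray) -> BackgroundEstimate:
    """Estimate the per-band background mean and sd.

    Background candidates are pixels above an Otsu threshold on luminance.
    When the Otsu split does not separate two populations by at least
    ~10 intensity units the frame is treated as object-free and the full
    image is used, so a pure-noise field is not split at its mean.
    """
    image = _check_rgb8(image)
    lum = image.mean(axis=2)
    if float(lum.std()) == 0.0:
        mask = np.ones(lum.shape, dtype=bool)
        method = "full-image"
    else:
        t = threshold_otsu(lum)
        bg_mask = lum > t
        fg_mask = ~bg_mask
        if (
            not bg_mask.any()
            or not fg_mask.any()
            or float(lum[bg_mask].mean() - lum[fg_mask].mean()) < _MIN_SEPARATION
        ):
            mask = np.ones(lum.shape, dtype=bool)
            method = "full-image"
        else:
            mask = bg_mask
            method = "otsu-luminance"
    frac = float(mask.mean())
    if frac < 0.10:
        raise FieldTooCrowdedError(
            f"field too crowded: only {frac:.1%} candidate background pixels"
        )
    pix = image[mask].astype(float)
    return BackgroundEstimate(
        mean_rgb=tuple(pix.mean(axis=0)),
        sd_rgb=tuple(pix.std(axis=0)),
        method=method,
    )


def segment_objects(
    image: np.ndarray,
    bg: BackgroundEstimate,
    min_deficit: float = DEFAULT_MIN_DEFICIT,
    min_object_area: float = 1.0,
) -> list[SegmentedObject]:
    """Segment dark objects as 8-connected components of deficient pixels.

    A pixel is foreground when its deficit from the background exceeds
    ``min_deficit`` in *every* band.  Components smaller than
    ``min_object_area`` pixels are dropped.
    """
    image = _check_rgb8(image)
    deficit = bg.mean - image.astype(float)
    fg = (deficit > min_deficit).all(axis=2)
    labels = cc_label(fg, connectivity=2)
    out: list[SegmentedObject] = []
    for region in regionprops(labels, intensity_image=image.astype(float)):
        if region.area < min_object_area:
            continue
        out.append(
            SegmentedObject(
                label=int(region.label),
                area_px=int(region.area),
                centroid=tuple(float(x) for x in region.centroid),
                mean_rgb=tuple(float(x) for x in region.intensity_mean),
                bbox=tuple(int(x) for x in region.bbox),
            )
        )
    return out


def largest_dark_region(image: np.ndarray) -> SegmentedObject:
    """Identify the conjugate-complex area of a low-resolution chip photo.

    Splits luminance with a global Otsu threshold and returns the largest
    8-connected dark component with its per-band mean — the "complex area
    separated from the rest of the image" used by mobile-image analysis,
    where individual cells are unresolvable.
    """
    image = _check_rgb8(image)
    lum = image.mean(axis=2)
    if float(lum.std()) == 0.0:
        raise FieldTooCrowdedError("flat image: no dark region to identify")
    fg = lum < threshold_otsu(lum)
    labels = cc_label(fg, connectivity=2)
    if labels.max() == 0:
        raise FieldTooCrowdedError("no dark region found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    regions = {r.label: r for r in regionprops(labels, intensity_image=image.astype(float))}
    region = regions[best]
    return SegmentedObject(
        label=best,
        area_px=int(region.area),
        centroid=tuple(float(x) for x in region.centroid),
        mean_rgb=tuple(float(x) for x in region.intensity_mean),
        bbox=tuple(int(x) for x in region.bbox),
    )


def crop_roi(image: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Crop a half-open ``(r0, c0, r1, c1)`` region of interest."""
    image = _check_rgb8(image)
    r0, c0, r1, c1 = bbox
    rows, cols = image.shape[:2]
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ConfigurationError(
            f"bbox {bbox} invalid for image of shape {(rows, cols)}"
        )
    return image[r0:r1, c0:c1].copy()


def objects_to_frame(objects: Sequence[SegmentedObject]) -> pd.DataFrame:
    """Tabulate segmented objects (one row per region)."""
    return pd.DataFrame(
        {
            "label": [o.label for o in objects],
            "area_px": [o.area_px for o in objects],
            "centroid_row": [o.centroid[0] for o in objects],
            "centroid_col": [o.centroid[1] for o in objects],
            "mean_R": [o.mean_rgb[0] for o in objects],
            "mean_G": [o.mean_rgb[1] for o in objects],
            "mean_B": [o.mean_rgb[2] for o in objects],
        }
    )


def frame_to_objects(df: pd.DataFrame) -> list[SegmentedObject]:
    """Rebuild :class:`SegmentedObject` records from a saved table."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SegmentedObject(
                label=int(row.label),
                area_px=int(row.area_px),
                centroid=(float(row.centroid_row), float(row.centroid_col)),
                mean_rgb=(float(row.mean_R), float(row.mean_G), float(row.mean_B)),
                bbox=(0, 0, 0, 0),
            )
        )
    return out
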