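"""Caldera detection: elliptically symmetric vertebral lesions.

In metastatic breast cancer many objects in bone — metastases, inflammatory
foci, sclerosing zones — present as radially symmetric "calderas" on
sagittal slices.  Their area, as a percentage of the selected vertebral
window, quantifies the partial-response axis over time.  Three intensity
classes are distinguished relative to the intervertebral-disc reference
intensity: BLACK (darker than the disc), WHITE (brighter), and ISO
(approximately equal, within a configurable relative tolerance).

Detection per class sweeps a binarization threshold over the class's
admissible intensity band; at each threshold the binary mask is decomposed
into 8-connected components, each component gets an ellipse fitted by
second-order image moments, components failing the ellipticity / size /
interiority filters are discarded, and the threshold retained is the one
maximizing the total retained ellipse area.  The sweep is recorded so the
optimality of the chosen threshold is checkable after the fact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .image_io import ImageFrame, ROIBox

logger = logging.getLogger("radiomarker")

__all__ = [
    "CalderaClass",
    "CalderaFilters",
    "CalderaEllipse",
    "CalderaResult",
    "reference_intensity",
    "detect_calderas",
    "detect_all",
]


class CalderaClass(Enum):
    """Lesion intensity relative to the intervertebral-disc reference."""

    BLACK = "BLACK"
    WHITE = "WHITE"
    ISO = "ISO"


@dataclass(frozen=True)
class CalderaFilters:
    """Component filters and sweep parameters for caldera detection.

    ``iso_tolerance`` is the relative half-width of the ISO band:
    intensities within ``iso_tolerance * reference`` of the reference count
    as "approximately equal" to the disc.  ``threshold_step`` is the integer
    sweep step over the 8-bit admissible band.  A component is retained when
    its pixel area is at least ``min_area_frac`` of the ROI, the ratio of
    its pixel area to its moments-fitted ellipse area lies within
    ``ellipticity_range``, its eccentricity does not exceed
    ``max_eccentricity``, and (when ``exclude_border``) it does not touch
    the ROI edge — a caldera is a lesion wholly inside the vertebral window,
    and the border test keeps a flooded background from masquerading as one.

    Before components are extracted the mask undergoes a binary opening
    with a square element of ``(2 * opening_radius + 1)`` pixels; this
    strips isolated noise pixels and thin noise bridges that would
    otherwise inflate the max-area threshold choice near the edge of the
    admissible band.  Set ``opening_radius = 0`` to disable.

    ``min_solidity`` rejects ragged components (area / convex-hull area):
    a genuine caldera is convex, while conglomerates of background noise
    pixels that happen to pass the moments-ellipse test are not.

    ``min_mask_coverage`` guards the threshold sweep itself: when the
    retained components explain less than this fraction of the binary
    mask's foreground, the threshold has leaked into background noise and
    is treated as segmenting nothing (its total is recorded as 0).  Without
    this guard the max-area selection always drifts to the noisiest
    admissible threshold, inflating areas by the attached noise halo.
    """

    iso_tolerance: float = 0.10
    threshold_step: int = 2
    min_area_frac: float = 0.005
    ellipticity_range: tuple[float, float] = (0.7, 1.3)
    max_eccentricity: float = 0.95
    exclude_border: bool = True
    opening_radius: int = 1
    min_solidity: float = 0.9
    min_mask_coverage: float = 0.5


@dataclass(frozen=True)
class CalderaEllipse:
    """One detected caldera: moments-fitted ellipse plus class and area."""

    center_row: float
    center_col: float
    semi_major_mm: float
    semi_minor_mm: float
    orientation_rad: float
    cls: CalderaClass
    area_pct: float  # pixel area of the component as % of the ROI


@dataclass
class CalderaResult:
    """Detection output: ellipses, per-class area %, chosen thresholds.

    ``sweep_by_class`` maps each class to the recorded ``(threshold,
    total_area_pct)`` pairs of its sweep, so threshold optimality can be
    audited.  For BLACK/WHITE the threshold is the binarization cut; for ISO
    it is the swept half-width of the band around the reference.
    """

    ellipses: list[CalderaEllipse]
    area_pct_by_class: dict[CalderaClass, float]
    chosen_threshold_by_class: dict[CalderaClass, float]
    reference_intensity: float
    sweep_by_class: dict[CalderaClass, list[tuple[float, float]]] = field(
        default_factory=dict
    )


def reference_intensity(frame: ImageFrame, disc_roi: ROIBox) -> float:
    """Median intensity of the intervertebral-disc ROI.

    The median (not the mean) is used so disc edge pixels and partial-volume
    effects do not drag the reference.
    """
    disc_roi.validate(frame.shape)
    px = frame.pixels[
        disc_roi.row0 : disc_roi.row0 + disc_roi.height,
        disc_roi.col0 : disc_roi.col0 + disc_roi.width,
    ]
    return float(np.median(px))


def _mask_for(
    cls: CalderaClass, px: np.ndarray, reference: float, threshold: float
) -> np.ndarray:
    if cls is CalderaClass.BLACK:
        return px <= threshold
    if cls is CalderaClass.WHITE:
        return px >= threshold
    return np.abs(px - reference) <= threshold  # ISO: threshold = half-width


def _sweep_values(
    cls: CalderaClass, reference: float, filters: CalderaFilters
) -> np.ndarray:
    step = filters.threshold_step
    tol = filters.iso_tolerance
    if cls is CalderaClass.BLACK:
        upper = (1.0 - tol) * reference  # stay below the ISO band
        return np.arange(step, math.floor(upper) + 1, step, dtype=float)
    if cls is CalderaClass.WHITE:
        lower = (1.0 + tol) * reference  # stay above the ISO band
        return np.arange(math.ceil(lower), 256, step, dtype=float)
    # ISO: half-widths inside the tolerance band
    upper = tol * reference
    return np.arange(step, math.floor(upper) + 1, step, dtype=float)


def _fit_components(
    mask: np.ndarray,
    cls: CalderaClass,
    filters: CalderaFilters,
    roi_area: int,
    spacing_mm: float,
) -> list[CalderaEllipse]:
    """8-connected components -> moments-fitted ellipses, filtered."""
    if filters.opening_radius > 0:
        size = 2 * filters.opening_radius + 1
        mask = ndimage.binary_opening(mask, structure=np.ones((size, size), bool))
    labeled = sk_label(mask, connectivity=2)
    min_area = filters.min_area_frac * roi_area
    lo, hi = filters.ellipticity_range
    rows, cols = mask.shape
    out: list[CalderaEllipse] = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        if filters.exclude_border:
            r0, c0, r1, c1 = region.bbox
            if r0 == 0 or c0 == 0 or r1 == rows or c1 == cols:
                continue
        semi_major_px = region.axis_major_length / 2.0
        semi_minor_px = region.axis_minor_length / 2.0
        if semi_minor_px <= 0:
            continue
        ellipse_area = math.pi * semi_major_px * semi_minor_px
        if ellipse_area <= 0 or not (lo <= region.area / ellipse_area <= hi):
            continue
        if region.eccentricity > filters.max_eccentricity:
            continue
        # a caldera is convex; ragged noise conglomerates are not
        if region.solidity < filters.min_solidity:
            continue
        out.append(
            CalderaEllipse(
                center_row=float(region.centroid[0]),
                center_col=float(region.centroid[1]),
                semi_major_mm=semi_major_px * spacing_mm,
                semi_minor_mm=semi_minor_px * spacing_mm,
                orientation_rad=float(region.orientation),
                cls=cls,
                area_pct=100.0 * region.area / roi_area,
            )
        )
    return out


def detect_calderas(
    frame: ImageFrame,
    roi: ROIBox,
    reference: float,
    cls: CalderaClass,
    filters: CalderaFilters | None = None,
) -> CalderaResult:
    """Detect calderas of one intensity class within the ROI.

    Sweeps the class's admissible threshold band in integer steps, keeps the
    threshold maximizing total retained component area (ties go to the
    smallest swept value, deterministically), and reports areas as % of the
    ROI.  An empty admissible band (e.g. reference 0 for BLACK) yields an
    empty result rather than an error.
    """
    if filters is None:
        filters = CalderaFilters()
    if not 0.0 <= reference <= 255.0:
        raise ValueError(f"reference intensity must be in [0, 255], got {reference}")
    roi.validate(frame.shape)
    px = frame.pixels[roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width]
    roi_area = px.size
    spacing = 1.0
    if frame.has_spacing:
        spacing = (frame.spacing_row_mm + frame.spacing_col_mm) / 2.0

    best_area = -1.0
    best_threshold = float("nan")
    best_ellipses: list[CalderaEllipse] = []
    sweep: list[tuple[float, float]] = []
    for threshold in _sweep_values(cls, reference, filters):
        mask = _mask_for(cls, px, reference, threshold)
        ellipses = _fit_components(mask, cls, filters, roi_area, spacing)
        total = sum(e.area_pct for e in ellipses)
        mask_px = int(mask.sum())
        retained_px = total / 100.0 * roi_area
        if mask_px > 0 and retained_px / mask_px < filters.min_mask_coverage:
            ellipses, total = [], 0.0  # noise-dominated threshold
        sweep.append((float(threshold), total))
        if total > best_area:  # strict: ties keep the smallest threshold
            best_area = total
            best_threshold = float(threshold)
            best_ellipses = ellipses

    total_pct = min(100.0, sum(e.area_pct for e in best_ellipses))
    return CalderaResult(
        ellipses=best_ellipses,
        area_pct_by_class={cls: total_pct},
        chosen_threshold_by_class={cls: best_threshold},
        reference_intensity=reference,
        sweep_by_class={cls: sweep},
    )


def detect_all(
    frame: ImageFrame,
    vert_roi: ROIBox,
    disc_roi: ROIBox,
    filters: CalderaFilters | None = None,
) -> CalderaResult:
    """Full caldera analysis: disc reference, then all three classes.

    The vertebral and disc ROIs should be disjoint; overlap only triggers a
    warning (the reference merely becomes less clean).
    """
    vert_roi.validate(frame.shape)
    disc_roi.validate(frame.shape)
    if vert_roi.overlaps(disc_roi):
        logger.warning("vertebra ROI and disc ROI overlap; reference may be biased")
    reference = reference_intensity(frame, disc_roi)

    merged = CalderaResult(
        ellipses=[],
        area_pct_by_class={},
        chosen_threshold_by_class={},
        reference_intensity=reference,
        sweep_by_class={},
    )
    for cls in CalderaClass:
        res = detect_calderas(frame, vert_roi, reference, cls, filters)
        merged.ellipses.extend(res.ellipses)
        merged.area_pct_by_class[cls] = res.area_pct_by_class[cls]
        merged.chosen_threshold_by_class[cls] = res.chosen_threshold_by_class[cls]
        merged.sweep_by_class[cls] = res.sweep_by_class[cls]
    return merged
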