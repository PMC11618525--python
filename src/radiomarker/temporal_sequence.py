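"""Longitudinal assembly of marker values into dated series.

Given a stack of dated frames with their ROIs, this module unifies the
physical resolution (every frame is resampled to the minimum pixel spacing
found in the sequence, so boundary-sum markers are comparable), optionally
normalizes intensities, runs the requested marker operators per frame, and
returns one date-sorted series per marker.  Series export to CSV and render
to annotated line plots — the treatment-course curves a clinician reads.

Repeat acquisitions on the same day are replicates: duplicate dates are
merged by mean (and logged).  ROIs are supplied per frame because the
vertebra position drifts between studies; there is no automatic
registration.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arcela import arcela_score
from .caldera import CalderaClass, CalderaFilters, detect_calderas, reference_intensity
from .contrast_marker import contrast_marker
from .image_io import ImageFrame, ROIBox, resample_to_spacing
from .normalization import NormalizationParams, normalize

logger = logging.getLogger("radiomarker")

__all__ = [
    "MarkerKind",
    "MarkerSample",
    "MarkerSeries",
    "FrameEntry",
    "build_series",
    "export_series",
    "read_series",
    "plot_series",
]


class MarkerKind(Enum):
    ARCELA = "ARCELA"
    CALDERA_BLACK = "CALDERA_BLACK"
    CALDERA_WHITE = "CALDERA_WHITE"
    CALDERA_ISO = "CALDERA_ISO"
    CONTRAST = "CONTRAST"


_CALDERA_OF = {
    MarkerKind.CALDERA_BLACK: CalderaClass.BLACK,
    MarkerKind.CALDERA_WHITE: CalderaClass.WHITE,
    MarkerKind.CALDERA_ISO: CalderaClass.ISO,
}

# the modality each marker is meant for (informational; mismatch warns)
_EXPECTED_MODALITY = {
    MarkerKind.ARCELA: "T1",
    MarkerKind.CALDERA_BLACK: "T2",
    MarkerKind.CALDERA_WHITE: "T2",
    MarkerKind.CALDERA_ISO: "T2",
    MarkerKind.CONTRAST: "T1C",
}


@dataclass(frozen=True)
class MarkerSample:
    """One (date, marker, value) measurement."""

    date: _dt.date
    marker: MarkerKind
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("marker values are non-negative")
        if self.marker is not MarkerKind.ARCELA and self.value > 100.0:
            raise ValueError(f"{self.marker.value} is a percentage, got {self.value}")


@dataclass
class MarkerSeries:
    """Date-ordered samples of one marker at one unified spacing."""

    marker: MarkerKind
    samples: list[MarkerSample] = field(default_factory=list)
    min_spacing_mm: float = 1.0

    @property
    def dates(self) -> list[_dt.date]:
        return [s.date for s in self.samples]

    @property
    def values(self) -> np.ndarray:
        return np.array([s.value for s in self.samples], dtype=float)


@dataclass(frozen=True)
class FrameEntry:
    """One acquisition: the frame, its vertebral ROI, optional disc ROI."""

    frame: ImageFrame
    roi: ROIBox
    disc_roi: Optional[ROIBox] = None
    date: Optional[_dt.date] = None  # fallback when the frame carries none

    def resolved_date(self) -> _dt.date:
        date = self.frame.acquisition_date or self.date
        if date is None:
            raise ValueError(
                "frame has no acquisition date and no fallback date was supplied"
            )
        return date


def _scaled_roi(roi: ROIBox, factor_row: float, factor_col: float, shape) -> ROIBox:
    box = roi.scaled(factor_row, factor_col)
    # clamp to the resampled frame (rounding can overshoot by a pixel)
    rows, cols = shape
    height = min(box.height, rows - box.row0)
    width = min(box.width, cols - box.col0)
    return ROIBox(box.row0, box.col0, height, width)


def build_series(
    entries: Sequence[FrameEntry],
    markers: set[MarkerKind] | Sequence[MarkerKind],
    normalize_intensity: bool = True,
    norm_params: NormalizationParams | None = None,
    caldera_filters: CalderaFilters | None = None,
) -> list[MarkerSeries]:
    """Compute the requested markers for every dated frame.

    All frames are resampled to the sequence's minimum pixel spacing before
    any marker runs; frames without spacing metadata are treated as 1 mm
    isotropic (warned).  Returns one series per requested marker, sorted by
    date, duplicate dates merged by mean.
    """
    markers = set(markers)
    if not entries:
        raise ValueError("no frames supplied")
    for kind in markers & set(_CALDERA_OF):
        for e in entries:
            if e.disc_roi is None:
                raise ValueError(f"{kind.value} requires a disc ROI on every frame")

    spacings = []
    for e in entries:
        if e.frame.has_spacing:
            spacings.extend([e.frame.spacing_row_mm, e.frame.spacing_col_mm])
        else:
            logger.warning("frame without pixel spacing treated as 1 mm isotropic")
            spacings.append(1.0)
    min_spacing = float(min(spacings))

    raw: dict[MarkerKind, dict[_dt.date, list[float]]] = {m: {} for m in markers}
    for entry in entries:
        date = entry.resolved_date()
        frame = entry.frame
        if not frame.has_spacing:
            from dataclasses import replace

            frame = replace(frame, spacing_row_mm=1.0, spacing_col_mm=1.0)
        factor_row = frame.spacing_row_mm / min_spacing
        factor_col = frame.spacing_col_mm / min_spacing
        frame = resample_to_spacing(frame, min_spacing)
        if normalize_intensity:
            frame = normalize(frame, norm_params)
        roi = _scaled_roi(entry.roi, factor_row, factor_col, frame.shape)
        disc_roi = (
            _scaled_roi(entry.disc_roi, factor_row, factor_col, frame.shape)
            if entry.disc_roi is not None
            else None
        )

        reference = (
            reference_intensity(frame, disc_roi) if disc_roi is not None else None
        )
        for kind in markers:
            expected = _EXPECTED_MODALITY[kind]
            if frame.modality.value not in (expected, "UNKNOWN"):
                logger.warning(
                    "%s computed on %s frame (usually computed on %s)",
                    kind.value,
                    frame.modality.value,
                    expected,
                )
            if kind is MarkerKind.ARCELA:
                value = arcela_score(frame, roi).value
            elif kind is MarkerKind.CONTRAST:
                value = contrast_marker(frame, roi).accumulation_pct
            else:
                res = detect_calderas(
                    frame, roi, reference, _CALDERA_OF[kind], caldera_filters
                )
                value = res.area_pct_by_class[_CALDERA_OF[kind]]
            raw[kind].setdefault(date, []).append(value)

    series_list = []
    for kind in sorted(markers, key=lambda m: m.value):
        by_date = raw[kind]
        samples = []
        for date in sorted(by_date):
            values = by_date[date]
            if len(values) > 1:
                logger.info(
                    "merged %d same-day %s acquisitions on %s by mean",
                    len(values),
                    kind.value,
                    date,
                )
            samples.append(MarkerSample(date, kind, float(np.mean(values))))
        series_list.append(
            MarkerSeries(marker=kind, samples=samples, min_spacing_mm=min_spacing)
        )
    return series_list


# ---------------------------------------------------------------------------
# Export / import / plotting
# ---------------------------------------------------------------------------


def export_series(series_list: Sequence[MarkerSeries], path: str | Path) -> None:
    """Write series to CSV with columns ``date,marker,value``."""
    rows = [
        {"date": s.date.isoformat(), "marker": s.marker.value, "value": repr(s.value)}
        for series in series_list
        for s in series.samples
    ]
    if not rows:
        raise ValueError("cannot export an empty series collection")
    pd.DataFrame(rows, columns=["date", "marker", "value"]).to_csv(path, index=False)


def read_series(path: str | Path) -> list[MarkerSeries]:
    """Read back a CSV written by :func:`export_series` (lossless round-trip)."""
    df = pd.read_csv(path, dtype={"date": str, "marker": str, "value": float})
    out = []
    for marker_name, group in df.groupby("marker", sort=True):
        kind = MarkerKind(marker_name)
        samples = [
            MarkerSample(_dt.date.fromisoformat(row.date), kind, float(row.value))
            for row in group.itertuples()
        ]
        samples.sort(key=lambda s: s.date)
        out.append(MarkerSeries(marker=kind, samples=samples))
    return out


def plot_series(
    series_list: Sequence[MarkerSeries],
    path: str | Path | None = None,
    events: Sequence[tuple[_dt.date, str]] | None = None,
):
    """Line plot of marker curves with optional therapy-event annotations.

    ``events`` draw dated vertical lines with labels (e.g. a change of CDK
    4/6 inhibitor).  Returns the matplotlib figure; saves a PNG when
    ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not series_list:
        raise ValueError("nothing to plot")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for series in series_list:
        ax.plot(series.dates, series.values, marker="o", label=series.marker.value)
    for date, label in events or []:
        ax.axvline(date, color="0.4", linestyle="--")
        ax.annotate(
            label,
            xy=(date, ax.get_ylim()[1]),
            rotation=90,
            va="top",
            fontsize=8,
        )
    ax.set_xlabel("acquisition date")
    ax.set_ylabel("marker value")
    ax.legend(fontsize=8)
    fig.autofmt_xdate()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig
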