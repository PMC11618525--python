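"""Reading MRI slices and plain images into a uniform grayscale frame.

Every downstream operator works on :class:`ImageFrame` — a single 2-D
grayscale slice with 8-bit intensity semantics (values in ``[0, 255]``,
stored as float64), physical pixel spacing in millimetres, and the DICOM
metadata the markers and the temporal module need (modality weighting,
acquisition date, TR/TE).

Coordinate convention (used by every module in the package): row-major,
0-based indices; ROI boxes are half-open, ``rows = [row0, row0 + height)``.
"""

from __future__ import annotations

import datetime as _dt
import logging

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("radiomarker")

__all__ = [
    "Modality",
    "ImageFrame",
    "ROIBox",
    "read_frame",
    "resample_to_spacing",
    "write_png",
    "write_fixture_dicom",
]


class Modality(Enum):
    """MRI weighting of a slice: T1, T2, contrast-enhanced T1, or unknown."""

    T1 = "T1"
    T2 = "T2"
    T1C = "T1C"
    UNKNOWN = "UNKNOWN"


@dataclass
class ImageFrame:
    """One grayscale slice with physical spacing and acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D float array with intensities in ``[0, 255]``.
    spacing_row_mm, spacing_col_mm:
        Physical size of one pixel in mm along rows / columns, or ``None``
        when the source carried no spacing information.
    modality:
        MRI weighting tag; purely informational for the marker operators.
    acquisition_date:
        Calendar date of the acquisition, or ``None``.
    repetition_time_ms, echo_time_ms:
        DICOM RepetitionTime / EchoTime, or ``None``.
    """

    pixels: np.ndarray
    spacing_row_mm: Optional[float] = None
    spacing_col_mm: Optional[float] = None
    modality: Modality = Modality.UNKNOWN
    acquisition_date: Optional[_dt.date] = None
    repetition_time_ms: Optional[float] = None
    echo_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.size and (px.min() < 0.0 or px.max() > 255.0):
            raise ValueError("pixel intensities must lie in [0, 255]")
        for name in ("spacing_row_mm", "spacing_col_mm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def has_spacing(self) -> bool:
        return self.spacing_row_mm is not None and self.spacing_col_mm is not None

    def crop(self, roi: "ROIBox") -> "ImageFrame":
        """Return a new frame holding only the ROI pixels (metadata kept)."""
        roi.validate(self.shape)
        sub = self.pixels[roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width]
        return replace(self, pixels=sub.copy())


@dataclass(frozen=True)
class ROIBox:
    """Rectangular region of interest: top-left corner plus extent.

    Half-open: covered rows are ``row0 .. row0 + height - 1``.  Markers are
    meaningless on tiny windows, so ``height, width >= 8`` is enforced.
    """

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError(
                f"ROI must be at least 8x8 pixels, got {self.height}x{self.width}"
            )
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate(self, frame_shape: tuple[int, int]) -> None:
        """Raise ``ValueError`` unless the box lies fully inside the frame."""
        rows, cols = frame_shape
        if self.row0 + self.height > rows or self.col0 + self.width > cols:
            raise ValueError(
                f"ROI {self} exceeds frame of shape {rows}x{cols}"
            )

    def scaled(self, row_factor: float, col_factor: float) -> "ROIBox":
        """ROI re-expressed after the frame was resampled by the given factors."""
        return ROIBox(
            row0=int(round(self.row0 * row_factor)),
            col0=int(round(self.col0 * col_factor)),
            height=max(8, int(round(self.height * row_factor))),
            width=max(8, int(round(self.width * col_factor))),
        )

    def overlaps(self, other: "ROIBox") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )

    @classmethod
    def parse(cls, text: str) -> "ROIBox":
        """Parse ``"row0,col0,height,width"`` (the CLI syntax)."""
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(
                f"ROI must be 'ROW0,COL0,HEIGHT,WIDTH', got {text!r}"
            )
        r0, c0, h, w = (int(p) for p in parts)
        return cls(r0, c0, h, w)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_MODALITY_HINTS = (
    ("t1c", Modality.T1C),
    ("+c", Modality.T1C),
    ("gad", Modality.T1C),
    ("t1", Modality.T1),
    ("t2", Modality.T2),
)


def _guess_modality(description: str) -> Modality:
    desc = description.lower()
    for hint, mod in _MODALITY_HINTS:
        if hint in desc:
            return mod
    return Modality.UNKNOWN


def _parse_dicom_date(value: str) -> Optional[_dt.date]:
    try:
        return _dt.datetime.strptime(str(value)[:8], "%Y%m%d").date()
    except (ValueError, TypeError):
        return None


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in {".dcm", ".dicom", ".ima"}:
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _read_dicom(path: Path) -> ImageFrame:
    import pydicom

    ds = pydicom.dcmread(path)
    raw = ds.pixel_array.astype(np.float64)
    if raw.ndim != 2:
        raise ValueError(f"only single-frame 2-D DICOM is supported, got shape {raw.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    raw = raw * slope + intercept
    # standardize to 8-bit grayscale before the operators run; data already
    # within [0, 255] (8-bit stores) passes through unchanged so fixture
    # round-trips are exact
    lo, hi = raw.min(), raw.max()
    if lo >= 0.0 and hi <= 255.0:
        px = raw
    elif hi == lo:
        px = np.zeros_like(raw)
    else:
        px = (raw - lo) / (hi - lo) * 255.0

    spacing_row = spacing_col = None
    if getattr(ds, "PixelSpacing", None) is not None and len(ds.PixelSpacing) == 2:
        spacing_row = float(ds.PixelSpacing[0])
        spacing_col = float(ds.PixelSpacing[1])
    else:
        logger.warning("DICOM %s has no PixelSpacing; spacing flagged absent", path)

    description = str(getattr(ds, "SeriesDescription", "") or "")
    date = None
    for attr in ("AcquisitionDate", "SeriesDate", "StudyDate"):
        value = getattr(ds, attr, None)
        if value:
            date = _parse_dicom_date(value)
            if date:
                break

    def _opt_float(attr: str) -> Optional[float]:
        v = getattr(ds, attr, None)
        return float(v) if v not in (None, "") else None

    return ImageFrame(
        pixels=px,
        spacing_row_mm=spacing_row,
        spacing_col_mm=spacing_col,
        modality=_guess_modality(description),
        acquisition_date=date,
        repetition_time_ms=_opt_float("RepetitionTime"),
        echo_time_ms=_opt_float("EchoTime"),
    )


def _read_plain_image(path: Path) -> ImageFrame:
    with Image.open(path) as img:
        gray = img.convert("L")  # ITU-R 601-2 luminance for color inputs
        px = np.asarray(gray, dtype=np.float64)
    return ImageFrame(pixels=px)


def read_frame(path: str | Path, roi: Optional[ROIBox] = None) -> ImageFrame:
    """Read a DICOM instance or an 8-bit image file into an :class:`ImageFrame`.

    Color inputs are converted to single-channel grayscale by luminance;
    DICOM pixel data has RescaleSlope/Intercept applied, then is min–max
    scaled to ``[0, 255]``.  When ``roi`` is given the returned frame is
    cropped to it.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read image file: {path}")
    frame = _read_dicom(path) if _is_dicom(path) else _read_plain_image(path)
    if roi is not None:
        frame = frame.crop(roi)
    return frame


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_to_spacing(frame: ImageFrame, target_mm: float) -> ImageFrame:
    """Resample a frame to isotropic ``target_mm`` pixel spacing (bilinear).

    The physical extent is preserved within one pixel; pixel content is
    bilinearly interpolated.  Bicubic interpolation is reserved for the
    contrast-accumulation marker, which specifies it explicitly.
    """
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    if not frame.has_spacing:
        raise ValueError(
            "frame has no pixel spacing; supply spacing_row_mm/spacing_col_mm "
            "manually before resampling"
        )
    rows, cols = frame.shape
    if frame.spacing_row_mm == target_mm and frame.spacing_col_mm == target_mm:
        return replace(frame, pixels=frame.pixels.copy())
    new_rows = max(1, int(round(rows * frame.spacing_row_mm / target_mm)))
    new_cols = max(1, int(round(cols * frame.spacing_col_mm / target_mm)))
    px = _sk_resize(
        frame.pixels,
        (new_rows, new_cols),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    px = np.clip(px, 0.0, 255.0)
    return replace(
        frame, pixels=px, spacing_row_mm=target_mm, spacing_col_mm=target_mm
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_png(frame: ImageFrame, path: str | Path) -> None:
    """Write the frame as an 8-bit grayscale PNG."""
    arr = np.clip(np.round(frame.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def write_fixture_dicom(frame: ImageFrame, path: str | Path) -> None:
    """Write a minimal single-frame MR DICOM instance (test fixtures).

    8-bit pixel data; PixelSpacing / dates / TR / TE copied from the frame.
    Round-tripping through :func:`read_frame` reproduces pixels exactly and
    spacing to 6 decimals.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.SeriesDescription = {
        Modality.T1: "sag T1",
        Modality.T2: "sag T2",
        Modality.T1C: "sag T1C",
        Modality.UNKNOWN: "sag",
    }[frame.modality]
    if frame.has_spacing:
        ds.PixelSpacing = [f"{frame.spacing_row_mm:.6f}", f"{frame.spacing_col_mm:.6f}"]
    if frame.acquisition_date is not None:
        ds.AcquisitionDate = frame.acquisition_date.strftime("%Y%m%d")
    if frame.repetition_time_ms is not None:
        ds.RepetitionTime = str(frame.repetition_time_ms)
    if frame.echo_time_ms is not None:
        ds.EchoTime = str(frame.echo_time_ms)

    arr = np.clip(np.round(frame.pixels), 0, 255).astype(np.uint8)
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
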