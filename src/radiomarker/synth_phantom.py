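"""Synthetic sagittal-vertebra phantoms with exact ground truth.

The clinical MRI behind the marker curves is not public, so every operator
in the package is exercised on phantoms: a rectangular "vertebral window"
over a uniform trabecular background, an intervertebral-disc band at the
top of the frame providing the caldera reference intensity, elliptical
lesions of the three caldera classes, and caricature textures for the three
classifier classes (normal bone / metastasis / hemangioma).

Ground truth is exact and machine-readable: the rendered pixel area of each
lesion mask, its analytic ellipse area, and its percentage of the vertebral
window.  The textures are caricatures tuned for operator separability, not
MR-physics realism — there is no k-space, coil, or relaxation modelling.

Default geometry: the disc band must differ in intensity from the vertebral
background (defaults 160 vs 100); otherwise ISO lesions, which by
definition match the disc intensity, would be indistinguishable from the
background they sit on.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .image_io import ImageFrame, Modality, ROIBox

__all__ = [
    "LesionClass",
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "make_sequence",
    "make_classification_set",
    "CLASS_LABELS",
]

CLASS_LABELS = ("norm", "mst", "hema")

DISC_BAND_ROWS = 16


class LesionClass(Enum):
    BLACK = "BLACK"  # darker than the disc reference
    WHITE = "WHITE"  # brighter than the disc reference
    ISO = "ISO"  # matches the disc reference
    MST_TEXTURE = "MST_TEXTURE"  # dark nidus + bright sclerotic rim
    HEMA_TEXTURE = "HEMA_TEXTURE"  # bright coarse-textured round blob

    @property
    def default_intensity(self) -> Optional[float]:
        return {"BLACK": 40.0, "WHITE": 220.0}.get(self.value)


@dataclass(frozen=True)
class LesionSpec:
    """One elliptical lesion: class, center (frame coords), semi-axes in px."""

    cls: LesionClass
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (row semi-axis, col semi-axis), px
    intensity: Optional[float] = None  # default per class; ISO -> disc intensity


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom frame."""

    size_px: tuple[int, int] = (128, 128)
    spacing_mm: float = 1.0
    background_intensity: float = 100.0
    disc_intensity: float = 160.0
    lesions: tuple[LesionSpec, ...] = ()
    noise_sd: float = 3.0
    seed: int = 0
    modality: Modality = Modality.T2
    acquisition_date: Optional[_dt.date] = None


@dataclass
class LesionTruth:
    cls: LesionClass
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    intensity: float
    pixel_area: int  # rendered mask pixels
    analytic_area: float  # pi * a * b
    area_pct: float  # pixel_area as % of the vertebral window


@dataclass
class PhantomTruth:
    """Exact ground truth for one rendered phantom."""

    spec: PhantomSpec
    vert_roi: ROIBox
    disc_roi: ROIBox
    lesions: list[LesionTruth] = field(default_factory=list)

    def area_pct(self, cls: LesionClass) -> float:
        """Summed rendered-area % of the window for one lesion class."""
        return sum(t.area_pct for t in self.lesions if t.cls is cls)


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], semi_axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = semi_axes
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[ImageFrame, PhantomTruth]:
    """Render one phantom frame; deterministic per ``spec.seed``.

    Layout: disc band in the top ``DISC_BAND_ROWS`` rows, vertebral window
    below it.  Lesions must lie inside the vertebral window.  Overlapping
    lesions are allowed; each truth record carries its own rendered area.
    """
    rows, cols = spec.size_px
    if rows <= DISC_BAND_ROWS + 8:
        raise ValueError("phantom too small for a disc band plus vertebral window")
    rng = np.random.default_rng(spec.seed)

    canvas = np.full((rows, cols), spec.background_intensity, dtype=np.float64)
    canvas[:DISC_BAND_ROWS, :] = spec.disc_intensity
    disc_roi = ROIBox(0, 0, DISC_BAND_ROWS, cols)
    vert_roi = ROIBox(DISC_BAND_ROWS, 0, rows - DISC_BAND_ROWS, cols)
    vert_area = vert_roi.height * vert_roi.width

    truth = PhantomTruth(spec=spec, vert_roi=vert_roi, disc_roi=disc_roi)
    for lesion in spec.lesions:
        a, b = lesion.semi_axes
        r, c = lesion.center
        if r - a < DISC_BAND_ROWS or r + a > rows or c - b < 0 or c + b > cols:
            raise ValueError(f"lesion {lesion} extends outside the vertebral window")
        mask = _ellipse_mask((rows, cols), lesion.center, lesion.semi_axes)
        intensity = lesion.intensity
        if intensity is None:
            intensity = (
                spec.disc_intensity
                if lesion.cls is LesionClass.ISO
                else lesion.cls.default_intensity
            )
        if lesion.cls is LesionClass.MST_TEXTURE:
            # dark nidus with the bright sclerotic rim of a healing
            # osteolytic metastasis
            core = _ellipse_mask((rows, cols), lesion.center, (0.65 * a, 0.65 * b))
            canvas[mask] = 210.0
            canvas[core] = 45.0 if intensity is None else intensity
            intensity = 45.0 if intensity is None else intensity
        elif lesion.cls is LesionClass.HEMA_TEXTURE:
            base = 210.0 if intensity is None else intensity
            coarse = ndimage.gaussian_filter(
                rng.normal(0.0, 30.0, size=(rows, cols)), sigma=2.0
            )
            canvas[mask] = base + coarse[mask]
            intensity = base
        else:
            canvas[mask] = intensity
        pixel_area = int(mask.sum())
        truth.lesions.append(
            LesionTruth(
                cls=lesion.cls,
                center=lesion.center,
                semi_axes=lesion.semi_axes,
                intensity=float(intensity),
                pixel_area=pixel_area,
                analytic_area=float(np.pi * a * b),
                area_pct=100.0 * pixel_area / vert_area,
            )
        )

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)

    frame = ImageFrame(
        pixels=canvas,
        spacing_row_mm=spec.spacing_mm,
        spacing_col_mm=spec.spacing_mm,
        modality=spec.modality,
        acquisition_date=spec.acquisition_date,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Longitudinal sequences
# ---------------------------------------------------------------------------


def _add_months(date: _dt.date, months: int) -> _dt.date:
    month = date.month - 1 + months
    year = date.year + month // 12
    month = month % 12 + 1
    day = min(date.day, 28)
    return _dt.date(year, month, day)


def make_sequence(
    base_spec: PhantomSpec,
    n_timepoints: int,
    lesion_trajectory: Callable[[int], float] | Sequence[float],
    start_date: _dt.date = _dt.date(2020, 1, 1),
    interval_months: int = 3,
) -> list[tuple[ImageFrame, PhantomTruth]]:
    """Dated phantom sequence whose lesion areas follow a trajectory.

    ``lesion_trajectory`` maps the timepoint index to an area scale factor
    (1.0 = the base spec's lesion area, 0.0 = lesion absent); semi-axes are
    scaled by its square root so rendered area tracks the factor.  Dates are
    spaced ``interval_months`` apart, mirroring a routine follow-up cadence
    of about 3 months.
    """
    if callable(lesion_trajectory):
        scales = [float(lesion_trajectory(t)) for t in range(n_timepoints)]
    else:
        scales = [float(s) for s in lesion_trajectory]
        if len(scales) != n_timepoints:
            raise ValueError("trajectory length must equal n_timepoints")

    out = []
    for t, scale in enumerate(scales):
        if scale < 0:
            raise ValueError("trajectory scales must be non-negative")
        axis_scale = float(np.sqrt(scale))
        lesions = []
        for lesion in base_spec.lesions:
            a, b = lesion.semi_axes
            # below ~1.5 px the raster is empty anyway; drop the lesion
            if axis_scale * a < 1.0 or axis_scale * b < 1.0:
                continue
            lesions.append(
                replace(lesion, semi_axes=(axis_scale * a, axis_scale * b))
            )
        spec_t = replace(
            base_spec,
            lesions=tuple(lesions),
            seed=base_spec.seed + t,
            acquisition_date=_add_months(start_date, t * interval_months),
        )
        out.append(make_phantom(spec_t))
    return out


# ---------------------------------------------------------------------------
# Classifier benchmark set
# ---------------------------------------------------------------------------


def _norm_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Normal bone: regular horizontal trabecular banding."""
    rows, cols = shape
    # jitter is kept small so the banding pattern — and hence the pHash —
    # is consistent across the class, as trabecular structure is in life
    period = rng.uniform(7.6, 8.4)
    phase = rng.uniform(-0.3, 0.3)
    rr = np.arange(rows)[:, None]
    img = 120.0 + 18.0 * np.sin(2.0 * np.pi * rr / period + phase)
    return np.broadcast_to(img, shape).copy()


def _mst_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Metastasis: dark nidus surrounded by a bright sclerotic ring."""
    rows, cols = shape
    img = np.full(shape, 120.0)
    center = (rows / 2 + rng.uniform(-3, 3), cols / 2 + rng.uniform(-3, 3))
    a = rng.uniform(12.0, 17.0)
    b = rng.uniform(10.0, 15.0)
    ring = _ellipse_mask(shape, center, (a, b))
    core = _ellipse_mask(shape, center, (0.65 * a, 0.65 * b))
    img[ring] = 205.0
    img[core] = 45.0
    return img


def _hema_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Hemangioma: bright round blob with coarse internal texture."""
    rows, cols = shape
    img = np.full(shape, 120.0)
    center = (rows / 2 + rng.uniform(-3, 3), cols / 2 + rng.uniform(-3, 3))
    radius = rng.uniform(13.0, 18.0)
    blob = _ellipse_mask(shape, center, (radius, radius))
    coarse = ndimage.gaussian_filter(rng.normal(0.0, 30.0, size=shape), sigma=2.0)
    img[blob] = 205.0 + coarse[blob]
    return img


_TEXTURES = {"norm": _norm_texture, "mst": _mst_texture, "hema": _hema_texture}


def make_classification_set(
    n_per_class: int,
    seed: int = 0,
    size_px: tuple[int, int] = (64, 64),
    noise_sd: float = 4.0,
) -> list[tuple[ImageFrame, str]]:
    """Labeled frames for the norm / mst / hema recognition benchmark.

    Per-class mean intensities are ordered hema > norm > mst core by
    construction.  Each frame is T2-tagged with 1 mm spacing.
    """
    if n_per_class < 5:
        raise ValueError("need at least 5 examples per class")
    rng = np.random.default_rng(seed)
    out: list[tuple[ImageFrame, str]] = []
    for label in CLASS_LABELS:
        texture = _TEXTURES[label]
        for _ in range(n_per_class):
            img = texture(rng, size_px)
            img = img + rng.normal(0.0, noise_sd, size=size_px)
            frame = ImageFrame(
                pixels=np.clip(img, 0.0, 255.0),
                spacing_row_mm=1.0,
                spacing_col_mm=1.0,
                modality=Modality.T2,
            )
            out.append((frame, label))
    return out
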