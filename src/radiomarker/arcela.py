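"""The Arcela image-complexity operator.

Quantifies how "busy" a vertebral window is: one image is more complex than
another if the summed boundaries of its constituent objects are larger.
Clinically this tracks the total-response axis — chaotic tumor angiogenesis
and peritumoral inflammation raise local intensity gradients, so a falling
Arcela score over a treatment course reads as a response.

Definition used here (scores are comparable only within this package):

    Arcela = mean over ROI pixels of |grad I| / 255

where the gradient is the Sobel operator scaled to central-difference units
(kernel sum 8), so a single unit step edge contributes its full contrast
exactly once across the two pixels adjacent to it.  The score is
dimensionless, zero exactly for a constant window, invariant under
intensity inversion, and lands in [0, 1] for realistic vertebral windows.

Frames belonging to a temporal sequence must be resampled to the sequence's
minimum pixel spacing before scoring so that boundary sums are compared at
a common physical resolution (the temporal module does this).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_io import ImageFrame, ROIBox

__all__ = ["ArcelaScore", "arcela_score"]


@dataclass(frozen=True)
class ArcelaScore:
    """Arcela complexity value for one ROI of one frame."""

    value: float
    roi: ROIBox
    frame_date: Optional[_dt.date] = None


def _sobel_magnitude(px: np.ndarray) -> np.ndarray:
    # reflect padding avoids a spurious boundary term from the crop edge
    gr = ndimage.sobel(px, axis=0, mode="reflect") / 8.0
    gc = ndimage.sobel(px, axis=1, mode="reflect") / 8.0
    return np.hypot(gr, gc)


def arcela_score(frame: ImageFrame, roi: ROIBox) -> ArcelaScore:
    """Compute the Arcela complexity of ``roi`` within ``frame``.

    Deterministic; requires a single-channel frame (grayscale conversion is
    the reader's job) and an ROI of at least 8x8 pixels fully inside it.
    """
    roi.validate(frame.shape)
    px = frame.pixels[roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width]
    if px.ndim != 2:
        raise ValueError("arcela_score expects a single-channel grayscale frame")
    mag = _sobel_magnitude(px)
    value = float(mag.sum() / (px.size * 255.0))
    return ArcelaScore(value=value, roi=roi, frame_date=frame.acquisition_date)
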