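"""Intensity normalization to a fixed target mean and variance.

MR intensity scales are arbitrary and drift between acquisitions, so the
markers and the classifier both operate on intensity-normalized frames.
The transform is the affine z-score remap

    out = (in - mean_in) / sd_in * sqrt(target_variance) + target_mean

followed by clamping to the 8-bit range.  The default targets (mean 108.0,
variance 2400.0) were fitted by the original system to a large corpus of
sagittal T1/T2 spine MRI; they are package defaults, overridable via
:class:`NormalizationParams` or config.

Two properties follow from the affine form (and are enforced by tests):
idempotence, and invariance to any positive global affine change of the
input intensities — both exact up to clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .image_io import ImageFrame

__all__ = ["NormalizationParams", "normalize"]

DEFAULT_TARGET_MEAN = 108.0
DEFAULT_TARGET_VARIANCE = 2400.0


@dataclass(frozen=True)
class NormalizationParams:
    """Target moments and output clamp bounds for intensity normalization."""

    target_mean: float = DEFAULT_TARGET_MEAN
    target_variance: float = DEFAULT_TARGET_VARIANCE
    clip_low: float = 0.0
    clip_high: float = 255.0

    def __post_init__(self) -> None:
        if not self.target_variance > 0:
            raise ValueError("target_variance must be positive")
        if not self.clip_low < self.clip_high:
            raise ValueError("clip_low must be below clip_high")


def normalize(frame: ImageFrame, params: NormalizationParams | None = None) -> ImageFrame:
    """Affinely remap frame intensities to the target mean and variance.

    Raises ``ValueError`` on zero-variance input (the remap is undefined).
    Metadata (spacing, modality, date, TR/TE) is preserved.
    """
    if params is None:
        params = NormalizationParams()
    px = frame.pixels
    mean_in = float(px.mean())
    var_in = float(px.var())
    if var_in == 0.0:
        raise ValueError("cannot normalize a zero-variance image")
    scale = np.sqrt(params.target_variance / var_in)
    out = (px - mean_in) * scale + params.target_mean
    out = np.clip(out, params.clip_low, params.clip_high)
    return replace(frame, pixels=out)
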