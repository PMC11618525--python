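"""Shared fixtures: phantoms and derived objects, generated at test time."""

import numpy as np
import pytest

from radiomarker import (
    ImageFrame,
    ROIBox,
    make_classification_set,
    make_phantom,
    phash,
)
from radiomarker.synth_phantom import LesionClass, LesionSpec, PhantomSpec


@pytest.fixture(scope="session")
def three_class_phantom():
    """Phantom with one lesion of each caldera class, plus its truth."""
    spec = PhantomSpec(
        lesions=(
            LesionSpec(LesionClass.BLACK, (50.0, 30.0), (12.0, 8.0)),
            LesionSpec(LesionClass.WHITE, (60.0, 75.0), (14.0, 9.0)),
            LesionSpec(LesionClass.ISO, (95.0, 50.0), (10.0, 10.0)),
        ),
        seed=1,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def lesion_free_phantom():
    return make_phantom(PhantomSpec(seed=2))


@pytest.fixture(scope="session")
def classification_set():
    """30 frames per class (norm / mst / hema), seeded."""
    return make_classification_set(30, seed=0)


@pytest.fixture(scope="session")
def labeled_codes(classification_set):
    return [phash(frame, label=label) for frame, label in classification_set]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def noise_frame(rng):
    """64x64 mid-gray frame with mild texture, 1 mm spacing."""
    px = np.clip(rng.normal(128.0, 25.0, (64, 64)), 0, 255)
    return ImageFrame(px, spacing_row_mm=1.0, spacing_col_mm=1.0)


@pytest.fixture()
def full_roi():
    return ROIBox(0, 0, 64, 64)
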