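"""Caldera detection: reference statistic, per-class detection, sweeps."""

import numpy as np
import pytest

from radiomarker import (
    CalderaClass,
    ImageFrame,
    ROIBox,
    detect_all,
    detect_calderas,
    reference_intensity,
)
from radiomarker.synth_phantom import LesionClass, LesionSpec, PhantomSpec, make_phantom


def _ellipse_frame(lesion_intensity, background=120.0, semi=(20.0, 10.0)):
    img = np.full((100, 100), background)
    rr, cc = np.ogrid[:100, :100]
    a, b = semi
    img[((rr - 50) / a) ** 2 + ((cc - 50) / b) ** 2 <= 1] = lesion_intensity
    return ImageFrame(img, spacing_row_mm=1.0, spacing_col_mm=1.0)


FULL = ROIBox(0, 0, 100, 100)


class TestReferenceIntensity:
    def test_constant_disc(self):
        frame = ImageFrame(np.full((20, 20), 150.0))
        assert reference_intensity(frame, ROIBox(0, 0, 20, 20)) == 150.0

    def test_median_not_mean(self):
        # 90 pixels of 100, 10 pixels of 200 in each row -> median 100
        px = np.full((10, 100), 100.0)
        px[:, 90:] = 200.0
        frame = ImageFrame(px)
        assert reference_intensity(frame, ROIBox(0, 0, 10, 100)) == 100.0


class TestSingleClassDetection:
    def test_structureless_roi_detects_nothing(self):
        frame = ImageFrame(np.full((64, 64), 120.0))
        for cls in CalderaClass:
            res = detect_calderas(frame, ROIBox(0, 0, 64, 64), 120.0, cls)
            assert res.ellipses == []
            assert res.area_pct_by_class[cls] == 0.0

    def test_bright_ellipse_recovered_as_white(self):
        frame = _ellipse_frame(220.0)
        res = detect_calderas(frame, FULL, 120.0, CalderaClass.WHITE)
        analytic_pct = np.pi * 20 * 10 / 10000 * 100  # 6.28%
        assert res.area_pct_by_class[CalderaClass.WHITE] == pytest.approx(
            analytic_pct, rel=0.05
        )
        assert len(res.ellipses) == 1
        e = res.ellipses[0]
        assert e.semi_major_mm >= e.semi_minor_mm > 0

    def test_dark_ellipse_is_black_not_white(self):
        frame = _ellipse_frame(30.0)
        black = detect_calderas(frame, FULL, 120.0, CalderaClass.BLACK)
        white = detect_calderas(frame, FULL, 120.0, CalderaClass.WHITE)
        assert black.area_pct_by_class[CalderaClass.BLACK] > 5.0
        assert white.area_pct_by_class[CalderaClass.WHITE] == 0.0

    def test_lesion_50_below_reference_never_white(self):
        frame = _ellipse_frame(70.0)  # 50 units below reference 120
        white = detect_calderas(frame, FULL, 120.0, CalderaClass.WHITE)
        assert white.area_pct_by_class[CalderaClass.WHITE] == 0.0

    def test_empty_admissible_band_yields_empty_result(self):
        frame = _ellipse_frame(30.0)
        res = detect_calderas(frame, FULL, 0.0, CalderaClass.BLACK)
        assert res.ellipses == []
        assert res.area_pct_by_class[CalderaClass.BLACK] == 0.0

    def test_bad_reference_rejected(self):
        frame = _ellipse_frame(30.0)
        with pytest.raises(ValueError):
            detect_calderas(frame, FULL, 300.0, CalderaClass.BLACK)


def _single_lesion_cases(cls, n=20, seed=123):
    rng = np.random.default_rng(seed)
    for k in range(n):
        a = rng.uniform(8, 16)
        b = rng.uniform(6, a)
        r = rng.uniform(16 + a + 2, 128 - a - 2)
        c = rng.uniform(b + 2, 128 - b - 2)
        spec = PhantomSpec(lesions=(LesionSpec(cls, (r, c), (a, b)),), seed=1000 + k)
        yield make_phantom(spec)


@pytest.mark.parametrize("cls", [LesionClass.BLACK, LesionClass.WHITE, LesionClass.ISO])
def test_area_recovery_and_threshold_optimality(cls):
    """Over seeded single-lesion phantoms: detected area within 5% relative
    of truth, and the chosen threshold's area dominates the whole sweep."""
    ccls = CalderaClass[cls.value]
    for frame, truth in _single_lesion_cases(cls):
        ref = reference_intensity(frame, truth.disc_roi)
        res = detect_calderas(frame, truth.vert_roi, ref, ccls)
        detected = res.area_pct_by_class[ccls]
        expected = truth.area_pct(cls)
        assert detected == pytest.approx(expected, rel=0.05)
        sweep = res.sweep_by_class[ccls]
        best = max(total for _, total in sweep)
        assert detected >= best - 1e-9


class TestDetectAll:
    def test_three_lesions_three_nonzero_classes(self, three_class_phantom):
        frame, truth = three_class_phantom
        res = detect_all(frame, truth.vert_roi, truth.disc_roi)
        nonzero = [cls for cls, pct in res.area_pct_by_class.items() if pct > 0]
        assert sorted(c.value for c in nonzero) == ["BLACK", "ISO", "WHITE"]
        for cls in CalderaClass:
            lesion_cls = LesionClass[cls.value]
            assert res.area_pct_by_class[cls] == pytest.approx(
                truth.area_pct(lesion_cls), rel=0.1
            )

    def test_lesion_free_phantom_all_zero(self, lesion_free_phantom):
        frame, truth = lesion_free_phantom
        res = detect_all(frame, truth.vert_roi, truth.disc_roi)
        assert all(pct == 0.0 for pct in res.area_pct_by_class.values())

    def test_overlapping_rois_warn_but_proceed(self, three_class_phantom, caplog):
        frame, truth = three_class_phantom
        overlapping_disc = ROIBox(10, 0, 16, 128)  # dips into the window
        with caplog.at_level("WARNING", logger="radiomarker"):
            detect_all(frame, truth.vert_roi, overlapping_disc)
        assert any("overlap" in rec.message for rec in caplog.records)

    def test_per_class_total_is_sum_of_ellipses(self, three_class_phantom):
        frame, truth = three_class_phantom
        res = detect_all(frame, truth.vert_roi, truth.disc_roi)
        for cls in CalderaClass:
            total = sum(e.area_pct for e in res.ellipses if e.cls is cls)
            assert res.area_pct_by_class[cls] == pytest.approx(min(total, 100.0))
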