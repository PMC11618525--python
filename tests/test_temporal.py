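"""Longitudinal series: assembly, sorting, merging, export, stability."""

import datetime
from dataclasses import replace

import numpy as np
import pytest

from radiomarker import (
    FrameEntry,
    MarkerKind,
    build_series,
    export_series,
    plot_series,
    read_series,
)
from radiomarker.synth_phantom import (
    LesionClass,
    LesionSpec,
    PhantomSpec,
    make_phantom,
    make_sequence,
)


def _entries_from(pairs, dates=None):
    out = []
    for i, (frame, truth) in enumerate(pairs):
        if dates is not None:
            frame = replace(frame, acquisition_date=dates[i])
        out.append(FrameEntry(frame, truth.vert_roi, truth.disc_roi))
    return out


@pytest.fixture(scope="module")
def shrinking_sequence():
    spec = PhantomSpec(
        lesions=(LesionSpec(LesionClass.WHITE, (70.0, 64.0), (16.0, 11.0)),),
        seed=11,
    )
    return make_sequence(spec, 6, lambda t: 1.0 - t / 5.0)


def test_identical_frames_give_constant_series(three_class_phantom):
    frame, truth = three_class_phantom
    dates = [datetime.date(2021, m, 1) for m in (1, 4, 7)]
    entries = [
        FrameEntry(replace(frame, acquisition_date=d), truth.vert_roi, truth.disc_roi)
        for d in dates
    ]
    series = build_series(entries, {MarkerKind.ARCELA, MarkerKind.CALDERA_WHITE})
    for s in series:
        assert len(set(np.round(s.values, 12))) == 1


def test_shrinking_white_lesion_series_decreases_to_zero(shrinking_sequence):
    entries = _entries_from(shrinking_sequence)
    (series,) = build_series(entries, {MarkerKind.CALDERA_WHITE})
    values = series.values
    assert np.all(np.diff(values) < 0)
    assert values[-1] == 0.0
    # truth is strictly decreasing by construction too
    truth_areas = [t.area_pct(LesionClass.WHITE) for _, t in shrinking_sequence]
    assert all(a > b for a, b in zip(truth_areas, truth_areas[1:]))


def test_out_of_order_frames_are_sorted(three_class_phantom):
    frame, truth = three_class_phantom
    dates = [datetime.date(2022, 9, 1), datetime.date(2021, 1, 1), datetime.date(2022, 1, 1)]
    entries = [
        FrameEntry(replace(frame, acquisition_date=d), truth.vert_roi, truth.disc_roi)
        for d in dates
    ]
    (series,) = build_series(entries, {MarkerKind.ARCELA})
    assert series.dates == sorted(dates)


def test_duplicate_dates_merge_by_mean(three_class_phantom, lesion_free_phantom):
    f1, t1 = three_class_phantom
    f2, _ = lesion_free_phantom
    d = datetime.date(2021, 6, 1)
    entries = [
        FrameEntry(replace(f1, acquisition_date=d), t1.vert_roi, t1.disc_roi),
        FrameEntry(replace(f2, acquisition_date=d), t1.vert_roi, t1.disc_roi),
    ]
    (series,) = build_series(entries, {MarkerKind.ARCELA}, normalize_intensity=False)
    assert len(series.samples) == 1
    from radiomarker import arcela_score

    expected = np.mean(
        [arcela_score(f1, t1.vert_roi).value, arcela_score(f2, t1.vert_roi).value]
    )
    assert series.samples[0].value == pytest.approx(expected, abs=1e-12)


def test_caldera_marker_requires_disc_roi(three_class_phantom):
    frame, truth = three_class_phantom
    frame = replace(frame, acquisition_date=datetime.date(2021, 1, 1))
    entries = [FrameEntry(frame, truth.vert_roi, None)]
    with pytest.raises(ValueError, match="disc"):
        build_series(entries, {MarkerKind.CALDERA_WHITE})


def test_missing_date_raises(three_class_phantom):
    frame, truth = three_class_phantom
    entries = [FrameEntry(replace(frame, acquisition_date=None), truth.vert_roi)]
    with pytest.raises(ValueError, match="date"):
        build_series(entries, {MarkerKind.ARCELA})


def test_affine_intensity_stability_with_normalization(shrinking_sequence):
    """A global affine intensity change, with normalization on, moves no
    series value by more than 1e-6."""
    entries = _entries_from(shrinking_sequence)
    scaled_entries = []
    for e in entries:
        scaled = replace(e.frame, pixels=np.clip(1.05 * e.frame.pixels + 3.0, 0, 255))
        assert (1.05 * e.frame.pixels + 3.0).max() < 255  # no clipping occurred
        scaled_entries.append(FrameEntry(scaled, e.roi, e.disc_roi))
    kinds = {MarkerKind.ARCELA, MarkerKind.CALDERA_WHITE}
    base = build_series(entries, kinds, normalize_intensity=True)
    scaled = build_series(scaled_entries, kinds, normalize_intensity=True)
    for s_base, s_scaled in zip(base, scaled):
        np.testing.assert_allclose(s_base.values, s_scaled.values, atol=1e-6)


def test_spacing_unification(three_class_phantom):
    frame, truth = three_class_phantom
    d = datetime.date(2021, 1, 1)
    coarse = replace(
        frame, spacing_row_mm=2.0, spacing_col_mm=2.0, acquisition_date=d
    )
    fine = replace(frame, acquisition_date=datetime.date(2021, 4, 1))
    entries = [
        FrameEntry(coarse, truth.vert_roi, truth.disc_roi),
        FrameEntry(fine, truth.vert_roi, truth.disc_roi),
    ]
    (series,) = build_series(entries, {MarkerKind.ARCELA})
    assert series.min_spacing_mm == 1.0


def test_export_round_trip(tmp_path, shrinking_sequence):
    entries = _entries_from(shrinking_sequence)
    series = build_series(entries, {MarkerKind.CALDERA_WHITE, MarkerKind.ARCELA})
    path = tmp_path / "series.csv"
    export_series(series, path)
    back = read_series(path)
    assert len(back) == len(series)
    for orig, re in zip(sorted(series, key=lambda s: s.marker.value), back):
        assert orig.marker is re.marker
        np.testing.assert_allclose(orig.values, re.values, atol=1e-9)
        assert orig.dates == re.dates


def test_single_sample_export(tmp_path, three_class_phantom):
    frame, truth = three_class_phantom
    frame = replace(frame, acquisition_date=datetime.date(2021, 1, 1))
    series = build_series(
        [FrameEntry(frame, truth.vert_roi)], {MarkerKind.ARCELA}
    )
    path = tmp_path / "one.csv"
    export_series(series, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 2  # header + 1 row


def test_empty_export_rejected(tmp_path):
    with pytest.raises(ValueError):
        export_series([], tmp_path / "empty.csv")


def test_plot_annotations(tmp_path, shrinking_sequence):
    entries = _entries_from(shrinking_sequence)
    series = build_series(entries, {MarkerKind.CALDERA_WHITE})
    events = [
        (datetime.date(2020, 4, 1), "inhibitor A"),
        (datetime.date(2020, 10, 1), "inhibitor B"),
    ]
    fig = plot_series(series, tmp_path / "plot.png", events=events)
    ax = fig.axes[0]
    vlines = [ln for ln in ax.lines if len(set(ln.get_xdata())) == 1]
    assert len(vlines) == 2
    assert (tmp_path / "plot.png").stat().st_size > 0
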