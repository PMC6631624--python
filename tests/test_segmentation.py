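"""Segmentation: overlap with ground truth, edge cases, invariances."""

import numpy as np
import pytest

from woundkinetics import (
    DensityField,
    ImageStack,
    RenderConfig,
    initial_wound_width,
    measure_area_series,
    render_timelapse,
    segment_stack,
    segment_wound,
)


def jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


def test_segmentation_overlaps_ground_truth(closing_stack):
    stack, gt = closing_stack
    for i in (0, 24, 48, 72):
        mask = segment_wound(stack.frames[i])
        assert jaccard(mask, gt[i]) >= 0.9


def test_confluent_frame_gives_empty_mask(study_grid, study_params):
    u = np.full((1, study_grid.n_nodes), study_params.u_hat)
    field = DensityField(np.array([0.0]), u, study_grid)
    stack, _ = render_timelapse(field, RenderConfig(frame_shape=(100, 800), seed=5), u_hat=study_params.u_hat)
    assert not segment_wound(stack.frames[0]).any()


def test_empty_field_gives_full_mask(study_grid, study_params):
    field = DensityField(np.array([0.0]), np.zeros((1, study_grid.n_nodes)), study_grid)
    stack, _ = render_timelapse(field, RenderConfig(frame_shape=(100, 800), seed=5), u_hat=study_params.u_hat)
    assert segment_wound(stack.frames[0]).all()


def test_constant_frame_warns_and_returns_full_mask():
    with pytest.warns(UserWarning, match="no texture"):
        mask = segment_wound(np.full((60, 80), 3.0))
    assert mask.all()


def test_nonfinite_frame_rejected():
    frame = np.ones((20, 20))
    frame[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        segment_wound(frame)


def test_mask_invariant_to_intensity_shift(closing_stack):
    stack, _ = closing_stack
    m0 = segment_wound(stack.frames[30])
    m1 = segment_wound(stack.frames[30] + 11.7)
    assert np.array_equal(m0, m1)


def test_areas_equal_pixel_count_times_pixel_area(closing_stack):
    stack, _ = closing_stack
    sub = ImageStack(stack.frames[:5], stack.times[:5], stack.pixel_size)
    series = segment_stack(sub)
    assert np.array_equal(
        series.areas, series.masks.sum(axis=(1, 2)) * stack.pixel_size**2
    )


class TestAreaSeries:
    def test_identical_frames_give_flat_series(self, closing_stack):
        stack, _ = closing_stack
        frames = np.repeat(stack.frames[:1], 4, axis=0)
        flat = ImageStack(frames, np.arange(4.0), stack.pixel_size)
        series = measure_area_series(flat)
        assert np.array_equal(series.a_over_a0, np.ones(4))

    def test_series_starts_at_one_and_matches_frame_count(self, closing_stack):
        stack, _ = closing_stack
        series = measure_area_series(stack)
        assert series.a_over_a0[0] == 1.0
        assert len(series.a_over_a0) == 73  # 18 h at 15-min intervals

    def test_recovered_series_tracks_ground_truth(self, closing_stack):
        stack, gt = closing_stack
        series = measure_area_series(stack)
        gt_areas = gt.sum(axis=(1, 2)).astype(float)
        gt_series = gt_areas / gt_areas[0]
        rms = np.sqrt(np.mean((series.a_over_a0 - gt_series) ** 2))
        assert rms < 0.03

    def test_closing_series_trend_is_non_increasing(self, closing_stack):
        stack, _ = closing_stack
        series = measure_area_series(stack)
        slope = np.polyfit(series.times, series.a_over_a0, 1)[0]
        assert slope <= 0

    def test_no_initial_wound_raises(self, study_grid, study_params):
        u = np.full((3, study_grid.n_nodes), study_params.u_hat)
        field = DensityField(np.array([0.0, 1.0, 2.0]), u, study_grid)
        stack, _ = render_timelapse(
            field, RenderConfig(frame_shape=(100, 800), seed=5), u_hat=study_params.u_hat
        )
        with pytest.raises(ValueError, match="A0 = 0"):
            measure_area_series(stack)

    def test_too_few_frames_rejected(self, closing_stack):
        stack, _ = closing_stack
        short = ImageStack(stack.frames[:2], stack.times[:2], stack.pixel_size)
        with pytest.raises(ValueError, match="at least 3"):
            measure_area_series(short)


class TestInitialWoundWidth:
    def test_perfect_stripe(self):
        mask = np.zeros((50, 300), dtype=bool)
        mask[:, 100:200] = True
        assert initial_wound_width(mask, pixel_size=2.0) == pytest.approx(200.0)

    def test_full_frame_mask(self):
        mask = np.ones((50, 300), dtype=bool)
        assert initial_wound_width(mask, pixel_size=2.0) == pytest.approx(600.0)

    def test_ragged_stripe_recovers_mean_width(self):
        rng = np.random.default_rng(3)
        rows, half = 200, 60
        mask = np.zeros((rows, 300), dtype=bool)
        jitter = rng.integers(-5, 6, size=(rows, 2))
        widths = []
        for r in range(rows):
            lo, hi = 150 - half + jitter[r, 0], 150 + half + jitter[r, 1]
            mask[r, lo:hi] = True
            widths.append(hi - lo)
        expected = float(np.mean(widths)) * 2.0
        assert initial_wound_width(mask, pixel_size=2.0) == pytest.approx(expected, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            initial_wound_width(np.zeros((10, 10), dtype=bool), pixel_size=1.0)
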