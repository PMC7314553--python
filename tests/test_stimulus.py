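"""Stimulus geometry, schedules, target decorrelation, texture, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lamsurf.stimulus as stim
from lamsurf.grid import VisualFieldGrid
from lamsurf.stimulus import (
    decorrelate_target_events,
    generate_texture,
    make_run_schedule,
    mouth_angle,
    pixel_to_luminance,
    predictor_correlation,
    render_bar_apertures,
    render_dynamic_control_movie,
    render_pacman_movie,
)

GRID = VisualFieldGrid(extent_deg=8.0, deg_per_pixel=0.05)
DISK_AREA = np.pi * (7.5 / 2) ** 2


class TestPacman:
    def test_static_occupied_fraction_matches_sector_arithmetic(self):
        movie = render_pacman_movie(duration_s=0.2, grid=GRID, static=True)
        occupied = movie.frames[0].sum() * movie.deg_per_pixel**2
        assert occupied / DISK_AREA == pytest.approx((360 - 70) / 360, rel=0.01)

    def test_zero_mouth_is_full_static_disk(self):
        movie = render_pacman_movie(mouth_arc_deg=0.0, duration_s=0.3, grid=GRID)
        assert np.array_equal(movie.frames[0], movie.frames[-1])
        occupied = movie.frames[0].sum() * movie.deg_per_pixel**2
        assert occupied == pytest.approx(DISK_AREA, rel=0.01)

    def test_disk_pixel_count_vs_closed_form_area(self):
        # brute-force rasterised area against the analytic disk area
        movie = render_pacman_movie(mouth_arc_deg=0.0, duration_s=1 / 30, grid=GRID)
        x, y = GRID.mesh()
        brute = int(((x**2 + y**2) <= 3.75**2).sum())
        assert movie.frames[0].sum() == brute
        assert brute * GRID.deg_per_pixel**2 == pytest.approx(DISK_AREA, rel=0.01)

    def test_mouth_angle_extremes_reach_amplitude(self):
        # one full cycle sampled at the frame rate: extremes within one
        # frame's quantisation of +-35 deg
        rate, freq = 60.0, 0.85
        t = np.arange(int(rate / freq)) / rate
        theta = mouth_angle(t, 35.0, freq)
        quant = 35.0 * 2 * np.pi * freq / rate  # max per-frame change
        assert theta.max() == pytest.approx(35.0, abs=quant)
        assert theta.min() == pytest.approx(-35.0, abs=quant)

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="cover"):
            render_pacman_movie(grid=VisualFieldGrid(5.0, 0.05), duration_s=0.1)

    def test_bad_frame_rate_raises(self):
        with pytest.raises(ValueError, match="frame rate"):
            render_pacman_movie(grid=GRID, duration_s=0.1, frame_rate=0.0)


class TestDynamicControl:
    def test_left_halffield_constant_over_time(self):
        movie = render_dynamic_control_movie(duration_s=1.2, grid=GRID)
        x, _ = GRID.mesh()
        left = movie.frames[:, x < 0]
        assert np.all(left == left[0])

    def test_occupied_fraction_matches_wedge_arcs(self):
        movie = render_dynamic_control_movie(duration_s=0.2, grid=GRID)
        occupied = movie.frames[0].sum() * movie.deg_per_pixel**2
        assert occupied / DISK_AREA == pytest.approx((220 + 65) / 360, rel=0.01)

    def test_zero_amplitude_is_static(self):
        movie = render_dynamic_control_movie(rot_amplitude_deg=0.0, duration_s=0.5, grid=GRID)
        assert np.all(movie.frames == movie.frames[0])

    def test_overlapping_wedges_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            render_dynamic_control_movie(
                stationary_arc_deg=220, rotating_arc_deg=65, rot_amplitude_deg=60,
                duration_s=0.1, grid=GRID,
            )

    def test_left_halffield_identical_across_all_three_conditions(self):
        """The three main-experiment movies are pixel-identical for x < 0."""
        kw = dict(duration_s=0.4, grid=GRID)
        rotating = render_pacman_movie(**kw)
        static = render_pacman_movie(static=True, **kw)
        control = render_dynamic_control_movie(**kw)
        x, _ = GRID.mesh()
        left = x < 0
        ref = static.frames[0][left]
        for movie in (rotating, static, control):
            assert np.all(movie.frames[:, left] == ref[None, :])


class TestBars:
    def test_configuration_count(self):
        movie, index = render_bar_apertures()
        assert movie.n_frames == 32
        assert len(index) == 32

    def test_single_configuration(self):
        movie, _ = render_bar_apertures(n_orientations=1, n_positions=1)
        assert movie.n_frames == 1

    @pytest.mark.parametrize("config", [0, 9, 17, 31])
    def test_band_width_perpendicular_to_orientation(self, config):
        grid = VisualFieldGrid(8.0, 0.1)
        movie, index = render_bar_apertures(grid=grid)
        ori = index.loc[config, "orientation_deg"]
        x, y = grid.mesh()
        normal = np.radians(ori + 90.0)
        proj = x * np.cos(normal) + y * np.sin(normal)
        occupied = movie.frames[config] > 0
        width = proj[occupied].max() - proj[occupied].min()
        expected = 1.25
        # pixel-centre rasterisation: up to one pixel diagonal of shrinkage
        assert abs(width - expected) <= np.sqrt(2) * grid.deg_per_pixel + 1e-9

    def test_bar_wider_than_field_raises(self):
        with pytest.raises(ValueError, match="width"):
            render_bar_apertures(bar_width_deg=99.0)


class TestRunSchedule:
    def test_paper_defaults_reproduce_run_totals(self):
        sched = make_run_schedule(seed=0)
        assert sched.n_volumes == 250
        assert sched.duration_s == pytest.approx(520.0, abs=0.5)
        assert len(sched.onsets_s) == 16
        # TR bookkeeping: 16 blocks x 5 TRs + 17 rests averaging 10 TRs
        assert sched.duration_volumes.sum() == 16 * 5
        assert sched.n_volumes - sched.duration_volumes.sum() == 17 * 10

    def test_zero_blocks_is_initial_rest_only(self):
        sched = make_run_schedule(n_blocks=0, seed=0)
        assert len(sched.onsets_s) == 0
        assert sched.n_volumes == 10  # 20.8 s at TR 2.079

    def test_counterbalanced_rest_counts(self):
        sched = make_run_schedule(seed=7)
        gaps = np.diff(sched.onsets_s) - sched.durations_s[:-1]
        closing = sched.duration_s - (sched.onsets_s[-1] + sched.durations_s[-1])
        rest_trs = np.rint(np.append(gaps, closing) / sched.tr_s).astype(int)
        counts = {k: int((rest_trs == k).sum()) for k in (9, 10, 11)}
        # 16 variable rests: equal counts with the remainder at the middle
        assert counts == {9: 5, 10: 6, 11: 5}

    def test_seed_reproducibility(self):
        a = make_run_schedule(seed=11)
        b = make_run_schedule(seed=11)
        assert np.array_equal(a.onsets_s, b.onsets_s)

    def test_non_tr_aligned_duration_raises(self):
        with pytest.raises(ValueError, match="integer multiple"):
            make_run_schedule(block_dur_s=10.0, seed=0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        n_blocks=st.integers(0, 20),
        seed=st.integers(0, 2**16),
        rests=st.lists(st.sampled_from([9, 10, 11, 12]), min_size=1, max_size=4, unique=True),
    )
    def test_schedule_conservation(self, n_blocks, seed, rests):
        """Sum of block and rest durations equals n_volumes x TR exactly."""
        tr = 2.079
        sched = make_run_schedule(
            n_blocks=n_blocks,
            rest_durations_s=tuple(r * tr for r in rests),
            seed=seed,
        )
        block_trs = sched.duration_volumes.sum()
        # rest TRs = everything that is not a block
        assert sched.n_volumes * tr == pytest.approx(sched.duration_s)
        assert sched.n_volumes >= block_trs
        if n_blocks:
            assert np.all(np.diff(sched.onsets_s) > 0)


class TestTargetEvents:
    def test_decorrelation_meets_paper_threshold_and_recomputes(self):
        sched = make_run_schedule(seed=3)
        events = decorrelate_target_events(sched, r_max=0.001, seed=3)
        assert abs(events.achieved_r) < 0.001
        # independent recomputation from the returned onsets
        r = predictor_correlation(sched, events.onsets_s)
        assert r == pytest.approx(events.achieved_r, abs=1e-12)

    def test_guard_period_and_iti(self):
        sched = make_run_schedule(seed=3)
        events = decorrelate_target_events(sched, r_max=0.01, seed=9)
        assert events.onsets_s.min() >= 15.0
        assert events.onsets_s.max() + events.duration_s <= sched.duration_s - 15.0
        itis = np.diff(events.onsets_s)
        assert np.all(itis >= 20.0 - 1e-9) and np.all(itis <= 40.0 + 1e-9)

    def test_seed_reproducibility(self):
        sched = make_run_schedule(seed=3)
        a = decorrelate_target_events(sched, r_max=0.01, seed=21)
        b = decorrelate_target_events(sched, r_max=0.01, seed=21)
        assert np.array_equal(a.onsets_s, b.onsets_s)

    def test_exhausted_iterations_report_best(self):
        sched = make_run_schedule(seed=3)
        with pytest.raises(RuntimeError, match="best"):
            decorrelate_target_events(sched, r_max=1e-12, max_iter=5, seed=0)


class TestTexture:
    def test_box_filter_reduces_sd_by_kernel_size(self, rng):
        # variance of a k x k box average of i.i.d. noise drops by k^2
        tex = generate_texture((400, 400), kernel_px=6, seed=5)
        raw = generate_texture((400, 400), kernel_px=1, seed=5)
        ratio = tex.image.std() / raw.image.std()
        assert ratio == pytest.approx(1 / 6, rel=0.15)

    def test_zero_sd_is_constant(self):
        tex = generate_texture((32, 32), gauss_sd=0.0, seed=0)
        assert np.allclose(tex.image, 40.0)

    def test_kernel_one_is_clipped_raw_noise(self):
        tex = generate_texture((64, 64), kernel_px=1, seed=8)
        raw = np.random.default_rng(8).normal(40.0, 60.0, (64, 64))
        assert np.array_equal(tex.image, np.clip(raw, 0, 255))

    def test_intensities_within_8bit_range(self):
        for clip_first in (True, False):
            tex = generate_texture((64, 64), seed=2, clip_before_filter=clip_first)
            assert tex.image.min() >= 0 and tex.image.max() <= 255


class TestCalibration:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 163.3), (1.0, -78.8 + 78.7 + 317.2 + 163.3), (-1.0, 78.8 + 78.7 - 317.2 + 163.3)],
    )
    def test_cubic_evaluation(self, x, expected):
        assert pixel_to_luminance(x) == pytest.approx(expected, abs=1e-10)

    def test_out_of_range_flagged_but_evaluated(self):
        with pytest.warns(UserWarning, match="range"):
            y = pixel_to_luminance(1.5)
        assert np.isfinite(y)
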