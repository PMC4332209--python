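"""TFI/TAC quantification, ROI selection, segmentation and tracking."""

import numpy as np
import pytest

from thromboflux import (AssayDesign, ThrombusSpec, generate_image_stack,
                         random_thrombus_specs)
from thromboflux.quant import (ROI, central_third_roi, default_threshold,
                               estimate_background, segment_thrombi,
                               select_analysis_thrombi, stack_to_traces,
                               total_area_covered, total_fluorescent_intensity,
                               track_thrombi)
from thromboflux.synth import Geometry, ImageStack


def make_stack(frames, dt=35.0, pixel_size_um=1.0):
    frames = np.asarray(frames)
    geom = Geometry(height_px=frames.shape[1], width_px=frames.shape[2],
                    pixel_size_um=pixel_size_um)
    t = np.arange(frames.shape[0], dtype=float) * dt
    return ImageStack(frames=frames, time_s=t, geometry=geom)


class TestTFI:
    def test_zero_frame(self):
        frame = np.zeros((20, 20))
        assert total_fluorescent_intensity(frame, ROI.full(frame)) == 0.0

    def test_two_pixel_frame(self):
        frame = np.zeros((20, 20))
        frame[3, 4], frame[10, 11] = 5.0, 7.0
        assert total_fluorescent_intensity(frame, ROI.full(frame)) == 12.0

    def test_background_subtraction_clips_at_zero(self):
        frame = np.full((10, 10), 2.0)
        frame[0, 0] = 10.0
        assert total_fluorescent_intensity(frame, ROI.full(frame), background=5.0) == 5.0

    def test_additive_over_disjoint_blobs(self, noiseless_design):
        a = ThrombusSpec(id=0, nucleation_time_s=35.0, center_row_px=40,
                         center_col_px=40, intensity_coeff=1.0)
        b = ThrombusSpec(id=1, nucleation_time_s=70.0, center_row_px=80,
                         center_col_px=120, intensity_coeff=2.0)
        bg = noiseless_design.background_level
        roi = ROI(0, 120, 0, 160)
        both, _ = generate_image_stack(noiseless_design, [a, b])
        only_a, _ = generate_image_stack(noiseless_design, [a])
        only_b, _ = generate_image_stack(noiseless_design, [b])
        k = -1  # last frame: both active
        tfi_both = total_fluorescent_intensity(both.frames[k], roi, bg)
        tfi_a = total_fluorescent_intensity(only_a.frames[k], roi, bg)
        tfi_b = total_fluorescent_intensity(only_b.frames[k], roi, bg)
        # sum-preserving quantization keeps each frame's total within 1 count
        assert tfi_both == pytest.approx(tfi_a + tfi_b, abs=3.0)

    def test_roi_outside_frame_rejected(self):
        frame = np.zeros((10, 10))
        with pytest.raises(ValueError, match="exceeds"):
            total_fluorescent_intensity(frame, ROI(0, 20, 0, 10))


class TestTAC:
    def test_counts_pixels_at_or_above_threshold(self):
        frame = np.zeros((10, 10))
        frame[:5, :5] = 9.0
        area_px, area_um2 = total_area_covered(frame, ROI.full(frame), 9.0, 1.0)
        assert (area_px, area_um2) == (25, 25.0)

    def test_threshold_above_max_gives_zero(self):
        frame = np.ones((10, 10))
        assert total_area_covered(frame, ROI.full(frame), 2.0) == (0, 0.0)

    def test_pixel_size_scales_area_quadratically(self):
        frame = np.ones((10, 10))
        _, um2 = total_area_covered(frame, ROI.full(frame), 1.0, pixel_size_um=0.5)
        assert um2 == pytest.approx(100 * 0.25)

    def test_lowering_threshold_never_decreases_area(self, rng):
        frame = rng.uniform(0, 100, (30, 30))
        roi = ROI.full(frame)
        areas = [total_area_covered(frame, roi, thr)[0]
                 for thr in np.linspace(100, 0, 11)]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))


class TestCentralThird:
    @pytest.mark.parametrize("height,expected", [
        (90, (30, 60)),
        (100, (33, 67)),
        (3, (1, 2)),
    ])
    def test_row_bounds(self, height, expected):
        roi = central_third_roi(Geometry(height_px=height, width_px=50))
        assert (roi.row_start, roi.row_stop) == expected
        assert roi.col_start == 0 and roi.col_stop == 50

    def test_too_short_channel_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            central_third_roi(Geometry(height_px=2, width_px=50))

    def test_boundary_row_is_inside(self):
        roi = central_third_roi(Geometry(height_px=90, width_px=50))
        assert roi.contains_row(30.0)
        assert not roi.contains_row(60.0)


class TestSegmentation:
    def test_two_separated_blobs_two_labels(self):
        frame = np.zeros((20, 20))
        frame[2:5, 2:5] = 10.0
        frame[10:13, 10:13] = 10.0
        labels = segment_thrombi(frame, 5.0)
        assert labels.max() == 2

    def test_empty_mask_no_labels(self):
        labels = segment_thrombi(np.zeros((20, 20)), 5.0)
        assert labels.max() == 0

    def test_diagonal_gap_bridged_by_8_connectivity(self):
        frame = np.zeros((10, 10))
        frame[2:5, 2:5] = 10.0
        frame[5:8, 5:8] = 10.0  # touches only at corner (4,4)-(5,5)
        labels = segment_thrombi(frame, 5.0)
        assert labels.max() == 1

    def test_small_components_discarded(self):
        frame = np.zeros((20, 20))
        frame[5, 5] = 10.0  # single pixel, below min_area_px=4
        frame[10:13, 10:13] = 10.0
        labels = segment_thrombi(frame, 5.0)
        assert labels.max() == 1
        assert labels[5, 5] == 0


class TestTracking:
    def test_static_blob_single_full_length_track(self):
        frame = np.zeros((30, 30))
        frame[10:14, 10:14] = 50.0
        stack = make_stack([frame] * 5)
        tracks = track_thrombi(stack, threshold=25.0, background=0.0)
        assert len(tracks) == 1
        tr = tracks[0]
        assert (tr.first_frame, tr.last_frame) == (0, 4)
        assert tr.area_px == [16] * 5

    def test_blob_in_last_frame_only(self):
        empty = np.zeros((30, 30))
        last = empty.copy()
        last[10:14, 10:14] = 50.0
        stack = make_stack([empty, empty, last])
        tracks = track_thrombi(stack, threshold=25.0, background=0.0)
        assert len(tracks) == 1
        assert tracks[0].first_frame == 2
        assert tracks[0].n_frames == 1

    def test_three_growing_blobs_recovered(self, noiseless_design, rng):
        specs = random_thrombus_specs(noiseless_design, 3, rng)
        stack, gt = generate_image_stack(noiseless_design, specs)
        tracks = track_thrombi(
            stack, threshold=noiseless_design.background_level + 1.0)
        assert len(tracks) == 3
        # each track starts once its blob clears the min-area gate
        starts = sorted(stack.time_s[t.first_frame] for t in tracks)
        taus = sorted(s.nucleation_time_s for s in specs)
        for start, tau in zip(starts, taus):
            assert tau <= start <= tau + 70.0

    def test_track_centroids_near_spec_centers(self, noiseless_design, rng):
        specs = random_thrombus_specs(noiseless_design, 3, rng)
        stack, _ = generate_image_stack(noiseless_design, specs)
        tracks = track_thrombi(
            stack, threshold=noiseless_design.background_level + 1.0)
        centers = {(round(s.center_row_px), round(s.center_col_px)) for s in specs}
        for tr in tracks:
            row, col = tr.mean_centroid
            assert any(abs(row - r) < 2 and abs(col - c) < 2 for r, c in centers)


class TestSelection:
    def _track_at(self, row):
        from thromboflux.quant import ThrombusTrack
        tr = ThrombusTrack(id=0, first_frame=0)
        tr.area_px, tr.area_um2 = [5], [5.0]
        tr.intensity, tr.centroid = [10.0], [(row, 50.0)]
        return tr

    def test_centroid_at_half_height_kept(self):
        geom = Geometry(height_px=90, width_px=100)
        kept = select_analysis_thrombi([self._track_at(45.0)], geom)
        assert len(kept) == 1 and kept[0].eligible_central_third

    def test_centroid_at_edge_excluded(self):
        geom = Geometry(height_px=90, width_px=100)
        kept = select_analysis_thrombi([self._track_at(0.0)], geom)
        assert kept == []

    def test_boundary_row_kept_half_open(self):
        geom = Geometry(height_px=90, width_px=100)
        kept = select_analysis_thrombi([self._track_at(30.0)], geom)
        assert len(kept) == 1

    def test_selected_matches_ground_truth_centers(self, noiseless_design, rng):
        roi = central_third_roi(Geometry(noiseless_design.frame_height_px,
                                         noiseless_design.frame_width_px))
        specs = random_thrombus_specs(noiseless_design, 3, rng)
        stack, _ = generate_image_stack(noiseless_design, specs)
        tracks = track_thrombi(
            stack, threshold=noiseless_design.background_level + 1.0)
        kept = select_analysis_thrombi(tracks, stack.geometry)
        expected = sum(roi.contains_row(s.center_row_px) for s in specs)
        assert len(kept) == expected


class TestStackToTraces:
    def test_background_only_stack_gives_zero_tfi(self, noiseless_design):
        spec = ThrombusSpec(id=0, nucleation_time_s=1e6, center_row_px=60,
                            center_col_px=80, intensity_coeff=1.0)
        stack, _ = generate_image_stack(noiseless_design, [spec])
        tfi, _ = stack_to_traces(stack)
        assert np.all(tfi.value == 0.0)

    def test_tfi_matches_analytic_sum(self, noiseless_design, rng):
        specs = random_thrombus_specs(noiseless_design, 3, rng)
        stack, gt = generate_image_stack(noiseless_design, specs)
        tfi, _ = stack_to_traces(stack)
        expected = gt.analytic_tfi(stack.time_s)
        assert np.all(np.abs(tfi.value - expected)
                      <= np.maximum(0.01 * expected, 1.0))

    def test_tac_nondecreasing_for_growing_blobs(self, noiseless_design, rng):
        specs = random_thrombus_specs(noiseless_design, 3, rng)
        stack, _ = generate_image_stack(noiseless_design, specs)
        _, tac = stack_to_traces(
            stack, threshold=noiseless_design.background_level + 1.0)
        assert np.all(np.diff(tac.value) >= 0)

    def test_translation_invariance_of_tfi_and_tac(self, noiseless_design):
        # small radius_coeff keeps every blob fully in frame, where the
        # metrics are translation invariant by construction
        base = ThrombusSpec(id=0, nucleation_time_s=70.0, center_row_px=50,
                            center_col_px=60, intensity_coeff=1.5,
                            radius_coeff=0.01)
        moved = ThrombusSpec(id=0, nucleation_time_s=70.0, center_row_px=58,
                             center_col_px=85, intensity_coeff=1.5,
                             radius_coeff=0.01)
        thr = noiseless_design.background_level + 1.0
        s1, _ = generate_image_stack(noiseless_design, [base])
        s2, _ = generate_image_stack(noiseless_design, [moved])
        tfi1, tac1 = stack_to_traces(s1, threshold=thr)
        tfi2, tac2 = stack_to_traces(s2, threshold=thr)
        np.testing.assert_allclose(tfi1.value, tfi2.value, atol=2.0)
        np.testing.assert_allclose(tac1.value, tac2.value, atol=3.0)

    def test_track_areas_bounded_by_tac(self, noiseless_design, rng):
        specs = random_thrombus_specs(noiseless_design, 3, rng)
        stack, _ = generate_image_stack(noiseless_design, specs)
        thr = noiseless_design.background_level + 1.0
        tracks = track_thrombi(stack, threshold=thr, min_area_px=1)
        _, tac = stack_to_traces(stack, threshold=thr)
        per_frame = np.zeros(len(stack))
        for tr in tracks:
            for k in range(tr.n_frames):
                per_frame[tr.first_frame + k] += tr.area_px[k]
        assert np.all(per_frame <= tac.value + 1e-9)


class TestDefaults:
    def test_background_is_first_frame_median(self, noiseless_design):
        spec = ThrombusSpec(id=0, nucleation_time_s=70.0, center_row_px=60,
                            center_col_px=80, intensity_coeff=1.0)
        stack, _ = generate_image_stack(noiseless_design, [spec])
        assert estimate_background(stack) == noiseless_design.background_level

    def test_otsu_threshold_separates_blob_from_background(self, noiseless_design):
        spec = ThrombusSpec(id=0, nucleation_time_s=35.0, center_row_px=60,
                            center_col_px=80, intensity_coeff=2.0)
        stack, _ = generate_image_stack(noiseless_design, [spec])
        thr = default_threshold(stack)
        assert thr > noiseless_design.background_level
        assert thr < stack.frames[-1].max()
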