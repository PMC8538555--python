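import numpy as np
import pytest

import colonmotion as cm
from colonmotion.pc import (
    lumen_rois,
    noise_floor,
    pc_mean_velocity,
    pc_peak_velocity,
    track_wall,
    wrap_suspicion,
)
from colonmotion.tagging import ROI


class TestLumenRois:
    def test_segmentation_recovers_ground_truth_mask_exactly(self, geometry):
        f = cm.prescribed_flow("plug", geometry, u0=0.5)
        acq = cm.PCAcquisition(n_frames=1, velocity_noise_sigma=0.0,
                               magnitude_noise_sigma=0.0, slice_x_position=125.0)
        seq = cm.render_pc_sequence(f, geometry, acq)
        full, _ = lumen_rois(seq.magnitude_frames[0])
        Y, Z = np.meshgrid(seq.y_coords, seq.z_coords, indexing="ij")
        # majority-rule ground truth on the renderer's 3x3 sub-voxel grid
        # (partial-volume boundary voxels count as fluid when more than
        # half their area is fluid)
        votes = np.zeros(Y.shape)
        offs = (np.arange(3) - 1) / 3 * acq.voxel_size
        for oy in offs:
            for oz in offs:
                votes += f.mask3(np.full_like(Y, 125.0), Y + oy, Z + oz, 0.0)
        truth = votes > 4.5
        assert np.array_equal(full.mask, truth)

    def test_central_box_covers_quarter_of_bounding_box(self):
        frame = np.zeros((80, 80))
        frame[20:60, 20:60] = 1.0
        full, central = lumen_rois(frame, central_fraction=0.25)
        ii, jj = np.nonzero(central.mask)
        assert (ii.max() - ii.min() + 1, jj.max() - jj.min() + 1) == (20, 20)
        assert central.mask.sum() == 400
        assert full.mask.sum() == 1600

    def test_featureless_frame_rejected(self):
        with pytest.raises(ValueError, match="contrast|segment"):
            lumen_rois(np.zeros((50, 50)))


class TestVelocityStatistics:
    def test_uniform_map_mean_equals_value_sd_zero(self):
        roi = ROI(np.ones((4, 4), bool))
        assert pc_mean_velocity(np.ones((4, 4)), roi) == (1.0, 0.0)

    def test_hand_computed_mean_and_sample_sd(self):
        v = np.array([[-1.0, 0.0], [0.0, 1.0]])
        mean, sd = pc_mean_velocity(v, ROI(np.ones((2, 2), bool)))
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(np.sqrt(2 / 3))  # ~0.816

    def test_peak_is_mean_of_k_extremes(self):
        v = np.zeros((4, 4))
        v.flat[:7] = [3, 2, 2, 1, 1, 1, 0]
        pos, neg = pc_peak_velocity(v, ROI(np.ones((4, 4), bool)), k=6)
        assert pos == pytest.approx(10 / 6)
        assert neg == pytest.approx(0.0)

    def test_six_hot_voxels(self):
        v = np.zeros((5, 5))
        v.flat[:6] = 2.0
        pos, _ = pc_peak_velocity(v, ROI(np.ones((5, 5), bool)), k=6)
        assert pos == pytest.approx(2.0)

    def test_all_zero_map_peaks_zero(self):
        pos, neg = pc_peak_velocity(np.zeros((3, 3)), ROI(np.ones((3, 3), bool)), k=6)
        assert pos == neg == 0.0

    def test_roi_smaller_than_k_rejected(self):
        small = np.zeros((3, 3), bool)
        small[0, :2] = True
        with pytest.raises(ValueError, match="fewer"):
            pc_peak_velocity(np.zeros((3, 3)), ROI(small), k=6)

    def test_uniform_field_mean_equals_both_peaks(self):
        roi = ROI(np.ones((5, 5), bool))
        v = np.full((5, 5), 0.7)
        mean, _ = pc_mean_velocity(v, roi)
        pos, neg = pc_peak_velocity(v, roi)
        assert mean == pytest.approx(0.7)
        assert pos == pytest.approx(mean)
        assert neg == pytest.approx(mean)

    def test_central_region_amplifies_centre_peaked_profile(self, geometry):
        f = cm.prescribed_flow("profile", geometry, u_centre=1.0)
        acq = cm.PCAcquisition(n_frames=1, velocity_noise_sigma=0.0,
                               magnitude_noise_sigma=0.0, slice_x_position=125.0)
        seq = cm.render_pc_sequence(f, geometry, acq)
        full, central = lumen_rois(seq.magnitude_frames[0])
        m_full, _ = pc_mean_velocity(seq.velocity_frames[0], full)
        m_cen, _ = pc_mean_velocity(seq.velocity_frames[0], central)
        assert abs(m_cen) > abs(m_full)


class TestNoiseFloor:
    def test_zero_noise_static_floor_is_zero(self, geometry):
        f = cm.prescribed_flow("static", geometry)
        acq = cm.PCAcquisition(n_frames=3, velocity_noise_sigma=0.0,
                               magnitude_noise_sigma=0.0, slice_x_position=125.0)
        seq = cm.render_pc_sequence(f, geometry, acq)
        full, _ = lumen_rois(seq.magnitude_frames[0])
        assert noise_floor(seq, full) == (0.0, 0.0)

    def test_injected_sigma_recovered_within_ten_percent(self, geometry):
        f = cm.prescribed_flow("static", geometry)
        acq = cm.PCAcquisition(n_frames=30, velocity_noise_sigma=0.0064,
                               slice_x_position=125.0, seed=3)
        seq = cm.render_pc_sequence(f, geometry, acq)
        full, _ = lumen_rois(seq.magnitude_frames[0])
        mean, sd = noise_floor(seq, full)
        assert sd == pytest.approx(0.0064, rel=0.10)
        assert abs(mean) < 3 * 0.0064 / np.sqrt(full.size * 30)

    def test_constant_offset_recovered(self, geometry):
        f = cm.prescribed_flow("plug", geometry, u0=0.01)
        acq = cm.PCAcquisition(n_frames=5, velocity_noise_sigma=0.0,
                               magnitude_noise_sigma=0.0, slice_x_position=125.0)
        seq = cm.render_pc_sequence(f, geometry, acq)
        full, _ = lumen_rois(seq.magnitude_frames[0])
        mean, _ = noise_floor(seq, full)
        assert mean == pytest.approx(0.01, abs=1e-6)


class TestWallTracking:
    def test_static_phantom_displacement_near_zero(self, geometry):
        f = cm.prescribed_flow("static", geometry)
        acq = cm.PCAcquisition(n_frames=4, slice_x_position=125.0, seed=2)
        seq = cm.render_pc_sequence(f, geometry, acq)
        wt = track_wall(seq)
        assert np.all(wt.valid)
        assert np.abs(wt.displacement).max() <= 0.3 * acq.voxel_size

    def test_contraction_plateau_and_relaxation_trough_recovered(
            self, filled_geometry, slow_flow, slow_program):
        k = 2
        acq = cm.PCAcquisition(n_frames=14, slice_x_position=filled_geometry.segment_centre(k),
                               seed=1)
        seq = cm.render_pc_sequence(slow_flow, filled_geometry, acq)
        wt = track_wall(seq)
        truth = np.array([
            cm.wall_displacement(slow_program, filled_geometry, k, t)
            for t in seq.frame_times
        ])
        plateau = wt.displacement[np.argmax(truth)]
        assert plateau == pytest.approx(10.40, abs=0.6)

    def test_relaxation_trough_recovered_with_fine_sampling(
            self, filled_geometry, slow_flow, slow_program):
        # the 0.4 s outward stroke needs sub-second frames to be caught
        k = 2
        t_trough = (slow_program.segment_delay(filled_geometry, k)
                    + slow_program.relax_duration)
        interval = t_trough / 35  # one frame lands exactly on the trough
        acq = cm.PCAcquisition(n_frames=37, frame_interval=interval,
                               slice_x_position=filled_geometry.segment_centre(k),
                               seed=1)
        seq = cm.render_pc_sequence(slow_flow, filled_geometry, acq)
        wt = track_wall(seq)
        assert wt.displacement[wt.valid].min() == pytest.approx(-3.20, abs=0.5)

    def test_low_contrast_frame_flagged(self):
        frames = np.ones((2, 40, 40)) * 0.5
        frames[0, 10:30, 10:30] = 1.0  # neutral frame has an edge
        wt = track_wall(frames, origin=(20.0, 20.0), direction=(0.0, -1.0),
                        min_gradient=0.05)
        assert wt.valid[0]
        assert not wt.valid[1]


class TestWrapSuspicion:
    def test_wrapped_jet_raises_flag(self):
        venc = 3.0
        v = np.full((20, 20), 2.9)
        v[8:12, 8:12] = -2.9  # aliased core hugging -venc inside +venc flow
        roi = ROI(np.ones((20, 20), bool))
        assert wrap_suspicion(v, roi, venc)

    def test_genuine_moderate_counterflow_not_flagged(self):
        venc = 3.0
        v = np.full((20, 20), 0.5)
        v[8:12, 8:12] = -1.0
        roi = ROI(np.ones((20, 20), bool))
        assert not wrap_suspicion(v, roi, venc)
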