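import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import colonmotion as cm
from colonmotion.tagging import ROI, cov, intensity_maps, tag_velocities
from colonmotion.synth import TagAcquisition


def _toy_seq(frames):
    """Wrap a raw (nt, nx, nz) stack in a TaggedSequence-like namespace."""
    frames = np.asarray(frames, dtype=np.float32)
    acq = TagAcquisition(n_frames=frames.shape[0], noise_sigma=0.0)

    class Seq:
        pass

    s = Seq()
    s.frames = frames
    s.acquisition = acq
    return s


class TestIntensityMaps:
    def test_constant_sequence_has_zero_sd(self):
        seq = _toy_seq(np.ones((4, 6, 5)) * 3.0)
        roi = ROI(np.ones((6, 5), bool))
        mi, sd = intensity_maps(seq, roi)
        assert np.allclose(mi, 3.0)
        assert np.allclose(sd, 0.0)

    def test_two_frame_hand_computation_sample_sd(self):
        stack = np.ones((2, 3, 3))
        stack[0, 1, 1], stack[1, 1, 1] = 1.0, 3.0
        seq = _toy_seq(stack)
        mi, sd = intensity_maps(seq, ROI(np.ones((3, 3), bool)))
        assert mi[1, 1] == pytest.approx(2.0)
        assert sd[1, 1] == pytest.approx(np.sqrt(2.0))  # n-1 denominator

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            intensity_maps(_toy_seq(np.ones((1, 3, 3))), ROI(np.ones((3, 3), bool)))

    def test_voxels_outside_roi_are_nan(self):
        seq = _toy_seq(np.ones((2, 4, 4)))
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        mi, sd = intensity_maps(seq, ROI(mask))
        assert np.isnan(mi[3, 3]) and np.isnan(sd[3, 3])

    def test_sd_map_peaks_mid_tube_on_slow_phantom(self, slow_tagged_seq,
                                                   slow_lumen_roi):
        # mixing motion is weakest at the caecal and flexure ends
        mi, sd = intensity_maps(slow_tagged_seq, slow_lumen_roi)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof = np.nanmean(np.where(slow_lumen_roi.mask, sd, np.nan), axis=1)
        x = slow_tagged_seq.x_coords

        def band(a, b):
            return np.nanmean(prof[(x >= a) & (x < b)])

        mid = band(100, 200)
        assert band(0, 50) < mid
        assert band(200, 250) < mid


class TestCoV:
    def test_zero_sd_gives_zero_cov(self):
        roi = ROI(np.ones((3, 3), bool))
        assert cov(np.ones((3, 3)), np.zeros((3, 3)), roi) == 0.0

    def test_hand_computed_ratio_of_means(self):
        roi = ROI(np.ones((2, 2), bool))
        assert cov(np.full((2, 2), 2.0), np.full((2, 2), 0.5), roi) == pytest.approx(25.0)

    def test_nonpositive_mean_intensity_rejected(self):
        roi = ROI(np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="positive"):
            cov(np.zeros((2, 2)), np.ones((2, 2)), roi)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_cov_invariant_under_intensity_rescaling(self, scale):
        rng = np.random.default_rng(12)
        stack = rng.uniform(0.5, 1.5, size=(5, 8, 8))
        roi = ROI(np.ones((8, 8), bool))
        c1 = cov(*intensity_maps(_toy_seq(stack), roi), roi)
        c2 = cov(*intensity_maps(_toy_seq(stack * scale), roi), roi)
        assert c2 == pytest.approx(c1, rel=1e-5)

    def test_cov_increases_with_slosh_amplitude(self, geometry):
        def cov_for(amplitude):
            f = cm.prescribed_flow("slosh", geometry, amplitude=amplitude,
                                   period=10.0)
            acq = cm.TagAcquisition(voxel_size=1.964, n_frames=50, seed=5)
            seq = cm.render_tagged_sequence(f, geometry, acq)
            roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
            return cm.cov_result(seq, roi).cov_percent

        assert cov_for(0.8) > cov_for(0.4)


class TestTagDetection:
    def test_undeformed_comb_detected_at_nominal_positions(self, geometry):
        f = cm.prescribed_flow("static", geometry)
        acq = cm.TagAcquisition(noise_sigma=0.0, n_frames=1)
        seq = cm.render_tagged_sequence(f, geometry, acq)
        roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
        dets = cm.detect_tags(seq.frames[0], seq.x_coords, seq.z_coords,
                              seq.nominal_tag_positions, acq.tag_spacing, roi,
                              tag_width=acq.tag_width)
        for det in dets:
            assert det.valid
            assert det.row_position == pytest.approx(det.nominal_position, abs=0.05)

    def test_overlapping_bands_flagged_invalid(self, geometry):
        f = cm.prescribed_flow("static", geometry)
        acq = cm.TagAcquisition(noise_sigma=0.0, n_frames=1,
                                nominal_tag_positions=(100.0, 103.0))
        seq = cm.render_tagged_sequence(f, geometry, acq)
        roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
        dets = cm.detect_tags(seq.frames[0], seq.x_coords, seq.z_coords,
                              seq.nominal_tag_positions, acq.tag_spacing, roi,
                              tag_width=acq.tag_width)
        assert not dets[0].valid
        assert not dets[1].valid
        assert "overlap" in dets[0].reason

    def test_displacement_never_reported_beyond_half_spacing(self, geometry):
        # a 3 cm/s plug moves bands 7.5 mm, past the 6 mm ambiguity limit:
        # whatever the detector returns must stay inside the search window
        f = cm.prescribed_flow("plug", geometry, u0=3.0)
        acq = cm.TagAcquisition(noise_sigma=0.0, n_frames=2)
        seq = cm.render_tagged_sequence(f, geometry, acq)
        roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
        tracks = cm.track_tags(seq, roi)
        for tr in tracks:
            reported = tr.centroid_displacement_mm[tr.valid]
            assert np.all(np.abs(reported) <= acq.tag_spacing / 2 + 1e-9)


class TestTagVelocities:
    def test_half_voxel_displacement_gives_quoted_resolution(self):
        acq = cm.TagAcquisition()
        # 0.491 mm over 250 ms
        v = (acq.voxel_size / 2) / acq.tag_delay / 10.0
        assert v == pytest.approx(0.1964)
        assert round(acq.velocity_uncertainty, 2) == 0.20

    def test_zero_displacement_zero_velocity(self, geometry):
        f = cm.prescribed_flow("static", geometry)
        seq = cm.render_tagged_sequence(
            f, geometry, cm.TagAcquisition(noise_sigma=0.0, n_frames=2))
        roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
        tracks = cm.track_tags(seq, roi)
        for tr in tracks:
            assert tr.v_avg_cms[tr.valid] == pytest.approx(0.0, abs=0.02)

    def test_plug_velocity_recovered_within_stated_uncertainty(self, geometry):
        f = cm.prescribed_flow("plug", geometry, u0=1.2)
        seq = cm.render_tagged_sequence(
            f, geometry, cm.TagAcquisition(noise_sigma=0.0, n_frames=2))
        roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
        tracks = cm.track_tags(seq, roi)
        v = np.concatenate([t.v_avg_cms[t.valid] for t in tracks])
        assert v.size > 0
        assert np.all(np.abs(v - 1.2) <= 0.20)

    def test_centroid_magnitude_bounded_by_peak_for_unidirectional_rows(
            self, geometry):
        f = cm.prescribed_flow("profile", geometry, u_centre=1.5)
        seq = cm.render_tagged_sequence(
            f, geometry, cm.TagAcquisition(noise_sigma=0.0, n_frames=2))
        roi = cm.neutral_lumen_roi(geometry, seq.x_coords, seq.z_coords)
        for tr in cm.track_tags(seq, roi):
            m = tr.valid
            assert np.all(np.abs(tr.centroid_displacement_mm[m])
                          <= np.abs(tr.peak_displacement_mm[m]) + 1e-9)

    def test_invalid_frames_carry_no_velocity(self):
        from colonmotion.tagging import TagDetection
        acq = cm.TagAcquisition()
        det_ok = TagDetection(1, 50.0, np.array([0.0]), np.array([51.0]), True)
        det_bad = TagDetection(1, 50.0, np.empty(0), np.empty(0), False, "lost")
        tracks = tag_velocities([[det_ok], [det_bad]], [50.0], acq)
        tr = tracks[0]
        assert tr.valid[0] and not tr.valid[1]
        assert np.isnan(tr.v_avg_cms[1])
        assert tr.v_avg_cms[0] == pytest.approx(0.4)  # 1 mm / 250 ms

    def test_direction_fidelity_on_noisy_phantom(self, slow_flow, slow_tracks):
        # recovered sign matches ground-truth section-mean sign in >= 95 %
        # of frames with non-negligible flow
        hits, total = 0, 0
        for tr in slow_tracks:
            truth = np.array([
                slow_flow.section_mean(tr.nominal_position, max(t - 0.125, 0.0))
                for t in tr.frame_times
            ])
            m = tr.valid & (np.abs(truth) > tr.uncertainty_cms)
            hits += np.sum(np.sign(tr.v_avg_cms[m]) == np.sign(truth[m]))
            total += int(m.sum())
        assert total > 50
        assert hits / total >= 0.95
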