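"""Ground-truth generators: closed-form statistics and determinism."""

import numpy as np
import pytest
from scipy import stats

from smkin import (
    AcquisitionMeta, CameraNoise, SimKineticParams, TrackSet,
    render_frames, simulate_bead_field, simulate_bleaching_survival,
    simulate_free_tracks, simulate_intensity_trace, simulate_two_state_tracks,
)
from smkin.core import BLEACH, FREE, InvalidMetadataError, MOVIE_END
from smkin.registration import ChannelMap
from smkin.tracking import detect_spots


class TestFreeTracks:
    def test_mean_squared_step_matches_brownian_closed_form(self, fast_meta):
        # 2D Brownian motion: E[dr^2] = 4*D*dt; dr^2 is exponential so
        # SE(mean) = mean/sqrt(n)
        ts = simulate_free_tracks(0.44, fast_meta, 100, seed=1)
        sq = []
        for tr in ts:
            sq.append(np.diff(tr.x_um) ** 2 + np.diff(tr.y_um) ** 2)
        sq = np.concatenate(sq)
        expected = 4 * 0.44 * 0.0175
        assert abs(sq.mean() - expected) < 3 * expected / np.sqrt(len(sq))

    def test_zero_diffusion_gives_zero_steps(self, fast_meta):
        ts = simulate_free_tracks(0.0, fast_meta, 5, seed=2)
        for tr in ts:
            assert np.all(np.diff(tr.x_um) == 0)
            assert np.all(np.diff(tr.y_um) == 0)

    def test_same_seed_bit_identical(self, fast_meta):
        a = simulate_free_tracks(0.44, fast_meta, 10, seed=3)
        b = simulate_free_tracks(0.44, fast_meta, 10, seed=3)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x_um, tb.x_um)
            np.testing.assert_array_equal(ta.y_um, tb.y_um)

    def test_invalid_metadata_rejected(self):
        with pytest.raises(InvalidMetadataError):
            AcquisitionMeta(frame_interval=-1.0, exposure_time=0.01)
        with pytest.raises(InvalidMetadataError):
            AcquisitionMeta(frame_interval=0.01, exposure_time=0.02)


class TestTwoStateTracks:
    def test_visible_bound_duration_is_minimum_of_exponentials(self):
        # unbinding at k_off competes with bleaching at k_bl, so visible
        # bound durations are Exp(k_off + k_bl)
        k_off, k_bl = 1 / 5.2, 1 / 30.0
        meta = AcquisitionMeta(0.1, 0.05, field_size=(200, 200),
                               n_frames=2000)
        p = SimKineticParams(k_off=k_off, k_bl=k_bl, k_bind=0.5)
        _, truth = simulate_two_state_tracks(p, meta, 120, (10.0, 10.0),
                                             seed=11)
        durs = truth.bound_durations(causes=("unbind", "bleach"))
        expected = 1 / (k_off + k_bl)
        assert len(durs) > 300
        assert abs(durs.mean() - expected) < 3 * expected / np.sqrt(len(durs))

    def test_bound_durations_are_exponential(self):
        meta = AcquisitionMeta(0.1, 0.05, field_size=(200, 200),
                               n_frames=2000)
        p = SimKineticParams(k_off=1 / 5.2, k_bl=1 / 30.0, k_bind=0.5)
        _, truth = simulate_two_state_tracks(p, meta, 120, (10.0, 10.0),
                                             seed=13)
        durs = truth.bound_durations(causes=("unbind", "bleach"))
        scale = 1 / (1 / 5.2 + 1 / 30.0)
        assert stats.kstest(durs, "expon", args=(0, scale)).pvalue > 0.01

    def test_no_binding_means_no_intervals(self, timelapse_meta):
        p = SimKineticParams(k_bind=0.0)
        _, truth = simulate_two_state_tracks(p, timelapse_meta, 10,
                                             (5.0, 5.0), seed=4)
        assert truth.intervals == []
        for labels in truth.labels.values():
            assert np.all(labels == FREE)

    def test_permanent_binding_censored_at_movie_end(self, timelapse_meta):
        p = SimKineticParams(k_off=0.0, k_bl=0.0, k_bind=5.0)
        _, truth = simulate_two_state_tracks(p, timelapse_meta, 10,
                                             (5.0, 5.0), seed=5)
        assert len(truth.intervals) == 10
        assert all(iv.end_cause == MOVIE_END for iv in truth.intervals)

    def test_labels_consistent_with_intervals(self, timelapse_meta,
                                              two_state_params):
        tracks, truth = simulate_two_state_tracks(
            two_state_params, timelapse_meta, 20, (5.0, 5.0), seed=6)
        dt = timelapse_meta.frame_interval
        for iv in truth.intervals:
            labels = truth.labels[iv.track_id]
            mid_frames = [k for k in range(len(labels))
                          if iv.start_s + 1e-9 < k * dt < iv.end_s - 1e-9]
            assert all(labels[k] == "BOUND" for k in mid_frames)

    def test_bleach_terminates_visibility(self, timelapse_meta):
        p = SimKineticParams(k_off=1 / 5.2, k_bl=1.0, k_bind=2.0)
        tracks, truth = simulate_two_state_tracks(p, timelapse_meta, 30,
                                                  (5.0, 5.0), seed=7)
        bleached = [iv for iv in truth.intervals if iv.end_cause == BLEACH]
        assert bleached
        for iv in bleached:
            labels = truth.labels[iv.track_id]
            after = labels[int(np.ceil(iv.end_s / 0.1)) + 1:]
            assert np.all(after == "BLEACHED")


class TestIntensityTrace:
    def test_single_molecule_level_recovered(self):
        # unit level 47 counts: the single-fluorophore intensity scale
        meta = AcquisitionMeta(1.0, 0.5, n_frames=200)
        trace, truth = simulate_intensity_trace([47.0, 0.0], [100.0, 100.0],
                                                noise_sd=5.0, meta=meta,
                                                seed=8)
        seg1 = trace.counts[:100]
        assert abs(seg1.mean() - 47.0) < 3 * 5.0 / np.sqrt(100)
        assert truth.change_times.tolist() == [100.0]

    def test_noiseless_trace_is_exact_step_function(self):
        meta = AcquisitionMeta(1.0, 0.5, n_frames=10)
        trace, _ = simulate_intensity_trace([10.0, 2.0], [5.0, 5.0], 0.0,
                                            meta, seed=9)
        np.testing.assert_array_equal(trace.counts,
                                      np.repeat([10.0, 2.0], 5))

    def test_three_fluorophore_staircase_truth(self):
        meta = AcquisitionMeta(1.0, 0.5, n_frames=40)
        u = 47.0
        _, truth = simulate_intensity_trace([3 * u, 2 * u, u, 0.0],
                                            [10.0] * 4, 1.0, meta, seed=10)
        assert len(truth.change_times) == 3
        assert np.all(np.diff(truth.change_levels) < 0)

    def test_empty_segment_list_rejected(self):
        meta = AcquisitionMeta(1.0, 0.5, n_frames=10)
        with pytest.raises(ValueError):
            simulate_intensity_trace([], [], 1.0, meta, seed=0)


class TestBleachingSurvival:
    @pytest.mark.parametrize("tau", [30.0, 300.0])
    def test_lifetime_mean(self, tau):
        n = 10_000
        s = simulate_bleaching_survival(tau, n, np.inf, seed=12)
        assert not s.censored.any()
        assert abs(s.durations.mean() - tau) < 3 * tau / np.sqrt(n)

    def test_zero_horizon_censors_everything(self):
        s = simulate_bleaching_survival(30.0, 100, 0.0, seed=13)
        assert s.censored.all()
        assert np.all(s.durations == 0.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            simulate_bleaching_survival(30.0, 0, np.inf, seed=0)


class TestRenderFrames:
    def test_stationary_emitter_round_trip(self):
        meta = AcquisitionMeta(0.1, 0.1, field_size=(32, 32), n_frames=2)
        tr = TrackSet([_static_track(1.60, 1.71, 2, 0.1)], meta)
        stack = render_frames(tr, None, psf_sigma=0.084,
                              photons_per_frame=2000, substeps=5,
                              noise=CameraNoise(100.0, 0.0), seed=1)
        locs = detect_spots(stack.data[0], pixel_size=0.105)
        assert len(locs) == 1
        assert abs(locs[0].x_px - 1.60 / 0.105) < 0.1
        assert abs(locs[0].y_px - 1.71 / 0.105) < 0.1

    def test_motion_blur_lowers_peak_amplitude(self):
        # a fast diffuser at long exposure smears over ~sqrt(4 D t_exp),
        # the "hardware filtering" that suppresses unbound molecules
        meta = AcquisitionMeta(0.5, 0.5, field_size=(48, 48), n_frames=2)
        rng = np.random.default_rng(2)
        steps = rng.normal(0, np.sqrt(2 * 0.44 * 0.5), size=(1, 2))
        xy = np.vstack([[1.5, 1.5], [1.5, 1.5] + steps[0]])
        fast = _track_from_xy(0, xy, 0.5)
        slow = _static_track(3.8, 3.8, 2, 0.5, track_id=1)
        stack = render_frames(TrackSet([fast, slow], meta), None,
                              substeps=29, noise=CameraNoise(100.0, 0.0),
                              seed=3)
        img = stack.data[0] - 100.0
        half = 24
        assert img[:half, :].max() < img[half:, :].max()

    def test_photon_totals_conserved_across_substeps(self):
        meta = AcquisitionMeta(0.1, 0.1, field_size=(48, 48), n_frames=2)
        tr = TrackSet([_static_track(2.4, 2.4, 2, 0.1)], meta)
        for substeps in (1, 7, 25):
            stack = render_frames(tr, None, photons_per_frame=1000,
                                  substeps=substeps,
                                  noise=CameraNoise(0.0, 0.0), seed=4)
            assert stack.data[0].sum() == pytest.approx(1000, rel=1e-6)

    def test_empty_trackset_gives_flat_offset(self):
        meta = AcquisitionMeta(0.1, 0.1, field_size=(32, 32), n_frames=3)
        stack = render_frames(TrackSet([], meta), None,
                              noise=CameraNoise(100.0, 0.0), seed=5)
        assert np.all(stack.data == 100.0)


class TestBeadField:
    def test_identity_transform_zero_noise(self):
        src, dst = simulate_bead_field(30, ChannelMap.identity(), 0.0,
                                       (50.0, 50.0), seed=6)
        np.testing.assert_allclose(src, dst)

    def test_underdetermined_bead_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_bead_field(3, ChannelMap.identity(order=2), 0.0,
                                (50.0, 50.0), seed=7)


def _static_track(x, y, n, dt, track_id=0):
    from smkin import Track
    return Track(track_id, np.arange(n), np.arange(n) * dt,
                 np.full(n, float(x)), np.full(n, float(y)))


def _track_from_xy(track_id, xy, dt):
    from smkin import Track
    n = len(xy)
    return Track(track_id, np.arange(n), np.arange(n) * dt,
                 xy[:, 0], xy[:, 1])
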