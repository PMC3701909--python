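"""Detection, linking, step-size statistics, and mobility classification."""

import numpy as np
import pytest
from scipy import stats

from smkin import (
    AcquisitionMeta, CameraNoise, SimKineticParams, Track, TrackSet,
    render_frames, simulate_free_tracks, simulate_two_state_tracks,
)
from smkin.core import BOUND, FREE, UNKNOWN
from smkin.tracking import (
    Localization, classify_bound_segments, detect_spots, detect_stack,
    fit_mobility_mixture, link_tracks, step_size_distribution,
)
from smkin.validation import label_accuracy


def _loc(frame, x_um, y_um, px=0.105):
    return Localization(frame, x_um / px, y_um / px, x_um, y_um, 100.0, 2.0)


class TestDetectSpots:
    def test_blank_frame_yields_nothing(self):
        rng = np.random.default_rng(0)
        frame = 100 + rng.normal(0, 2, size=(64, 64))
        assert detect_spots(frame) == []

    def test_two_emitters_ten_pixels_apart(self):
        meta = AcquisitionMeta(0.1, 0.1, field_size=(48, 48), n_frames=2)
        px = 0.105
        pos = [(15.0, 20.0), (25.0, 20.0)]  # pixels, 10 px apart
        tracks = [Track(i, np.arange(2), np.arange(2) * 0.1,
                        np.full(2, x * px), np.full(2, y * px))
                  for i, (x, y) in enumerate(pos)]
        stack = render_frames(TrackSet(tracks, meta), None, psf_sigma=0.084,
                              photons_per_frame=2000, substeps=1,
                              noise=CameraNoise(100.0, 2.0), seed=1)
        locs = detect_spots(stack.data[0])
        assert len(locs) == 2
        found = sorted((l.x_px, l.y_px) for l in locs)
        for (fx, fy), (tx, ty) in zip(found, pos):
            assert abs(fx - tx) < 0.2 and abs(fy - ty) < 0.2

    def test_band_order_validated(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((32, 32)), band_low=3.0, band_high=1.0)


class TestLinkTracks:
    def test_single_molecule_full_length_track(self, timelapse_meta):
        locs = [[_loc(f, 5.0 + 0.01 * f, 5.0)] for f in range(50)]
        ts = link_tracks(locs, timelapse_meta, max_disp=0.5)
        assert len(ts) == 1
        assert len(ts[0]) == 50

    def test_distant_molecules_never_swap(self, timelapse_meta):
        # two diffusers kept > max_disp apart: optimal assignment must
        # never exchange their identities
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            a = np.cumsum(rng.normal(0, 0.05, size=(n, 2)), axis=0) + [2, 2]
            b = np.cumsum(rng.normal(0, 0.05, size=(n, 2)), axis=0) + [8, 8]
            locs = [[_loc(f, *a[f]), _loc(f, *b[f])] for f in range(n)]
            ts = link_tracks(locs, timelapse_meta, max_disp=1.0)
            assert len(ts) == 2
            for tr in ts:
                start_near_a = np.hypot(tr.x_um[0] - a[0, 0],
                                        tr.y_um[0] - a[0, 1]) < 1
                ref = a if start_near_a else b
                d = np.hypot(tr.x_um - ref[tr.frame, 0],
                             tr.y_um - ref[tr.frame, 1])
                assert np.all(d < 0.5), f"identity swap at seed {seed}"

    def test_gap_closing_spans_missed_detection(self, timelapse_meta):
        locs = [[_loc(f, 3.0, 3.0)] if f != 10 else []
                for f in range(21)]
        ts = link_tracks(locs, timelapse_meta, max_disp=0.5, max_gap=1)
        assert len(ts) == 1
        assert ts[0].frame.tolist() == [f for f in range(21) if f != 10]

    def test_no_gap_closing_splits_track(self, timelapse_meta):
        locs = [[_loc(f, 3.0, 3.0)] if f not in (10, 11) else []
                for f in range(21)]
        ts = link_tracks(locs, timelapse_meta, max_disp=0.5, max_gap=1)
        assert len(ts) == 2


class TestStepSizeDistribution:
    def test_rms_step_matches_rayleigh_closed_form(self, fast_meta):
        ts = simulate_free_tracks(0.44, fast_meta, 100, seed=21)
        s = step_size_distribution(ts, lag=1)
        rms = np.sqrt(np.mean(s.dr ** 2))
        expected = np.sqrt(4 * 0.44 * 0.0175)   # 0.1755 um
        se = expected / (2 * np.sqrt(len(s)))   # delta method on sqrt
        assert abs(rms - expected) < 3 * se

    def test_lag_two_scales_by_sqrt_two(self, fast_meta):
        ts = simulate_free_tracks(0.44, fast_meta, 100, seed=22)
        r1 = np.sqrt(np.mean(step_size_distribution(ts, 1).dr ** 2))
        r2 = np.sqrt(np.mean(step_size_distribution(ts, 2).dr ** 2))
        assert r2 / r1 == pytest.approx(np.sqrt(2), rel=0.03)

    def test_single_sample_track_contributes_nothing(self, timelapse_meta):
        tr = Track(0, [0], [0.0], [1.0], [1.0])
        s = step_size_distribution(TrackSet([tr], timelapse_meta), 1)
        assert len(s) == 0

    def test_magnitudes_match_components(self, fast_meta):
        ts = simulate_free_tracks(0.44, fast_meta, 10, seed=23)
        s = step_size_distribution(ts, 1)
        np.testing.assert_allclose(s.dr, np.hypot(s.dx, s.dy))


class TestMobilityMixture:
    def test_two_component_recovery(self):
        # equal mixture of bilayer-fast and bound-slow diffusion at the
        # long-exposure lag: both D's within 10%, fractions within 0.05
        meta = AcquisitionMeta(0.5, 0.5, field_size=(500, 500), n_frames=51)
        for seed in range(20):
            fast = simulate_free_tracks(0.44, meta, 100, seed=1000 + seed)
            slow = simulate_free_tracks(0.005, meta, 100, seed=2000 + seed)
            tracks = fast.tracks + [
                Track(100 + t.track_id, t.frame, t.t_s, t.x_um, t.y_um)
                for t in slow]
            s = step_size_distribution(TrackSet(tracks, meta), 1)
            fit = fit_mobility_mixture(s, 0.5)
            assert fit.n_components == 2
            assert fit.d_fast == pytest.approx(0.44, rel=0.10)
            assert fit.d_slow == pytest.approx(0.005, rel=0.10)
            assert fit.f_slow == pytest.approx(0.5, abs=0.05)

    def test_unimodal_sample_selects_one_component(self, fast_meta):
        # no cells present: a single free population, one-component model
        ts = simulate_free_tracks(0.44, fast_meta, 100, seed=31)
        fit = fit_mobility_mixture(step_size_distribution(ts, 1), 0.0175)
        assert fit.n_components == 1
        se = 0.44 / np.sqrt(len(step_size_distribution(ts, 1)))
        assert abs(fit.d_fast - 0.44) < 3 * se

    def test_too_small_or_degenerate_sample_rejected(self):
        from smkin.tracking import StepSample
        with pytest.raises(ValueError):
            fit_mobility_mixture(StepSample(1, np.ones(10), np.ones(10),
                                            np.zeros(10)), 0.5)
        zeros = np.zeros(100)
        with pytest.raises(ValueError):
            fit_mobility_mixture(StepSample(1, zeros, zeros, zeros), 0.5)


class TestClassification:
    def _fit_and_classify(self, tracks, dt, window=3):
        fit = fit_mobility_mixture(step_size_distribution(tracks, 1), dt)
        return classify_bound_segments(tracks, fit, window)

    def test_two_state_labels_beat_95_percent(self):
        meta = AcquisitionMeta(0.1, 0.05, field_size=(200, 200),
                               n_frames=1200)
        p = SimKineticParams(k_off=1 / 5.2, k_bl=1 / 30, k_bind=0.5)
        tracks, truth = simulate_two_state_tracks(p, meta, 60, (10.0, 10.0),
                                                  seed=41)
        labeled, _ = self._fit_and_classify(tracks, 0.1)
        acc, n = label_accuracy(labeled, tracks, truth, match_radius=1e-6)
        assert n > 10_000
        assert acc >= 0.95

    def test_all_free_sample_rarely_labeled_bound(self, fast_meta):
        ts = simulate_free_tracks(0.44, fast_meta, 50, seed=42)
        # classification threshold from a genuine two-state fit
        meta2 = AcquisitionMeta(0.0175, 0.0175, field_size=(64, 64),
                                n_frames=200)
        slow = simulate_free_tracks(0.005, meta2, 50, seed=43)
        mixed = TrackSet(ts.tracks + [Track(50 + t.track_id, t.frame, t.t_s,
                                            t.x_um, t.y_um) for t in slow],
                         fast_meta)
        fit = fit_mobility_mixture(step_size_distribution(mixed, 1), 0.0175)
        labeled, _ = classify_bound_segments(ts, fit, 3)
        states = np.concatenate([t.state for t in labeled])
        assert (states == BOUND).mean() < 0.01

    def test_short_track_labeled_unknown(self, timelapse_meta,
                                         two_state_params):
        tracks, _ = simulate_two_state_tracks(two_state_params,
                                              timelapse_meta, 30,
                                              (5.0, 5.0), seed=44)
        fit = fit_mobility_mixture(step_size_distribution(tracks, 1), 0.1)
        short = Track(999, [0, 1, 2], [0.0, 0.1, 0.2],
                      [1.0, 1.1, 1.2], [1.0, 1.0, 1.0])
        labeled, dwells = classify_bound_segments(
            TrackSet([short], timelapse_meta), fit, window=3)
        assert np.all(labeled[0].state == UNKNOWN)
        assert len(dwells) == 0

    def test_dwell_censoring_flags(self, timelapse_meta):
        # permanently bound molecule: its one dwell touches the movie end
        p = SimKineticParams(k_off=0.0, k_bl=0.0, k_bind=50.0)
        tracks, _ = simulate_two_state_tracks(p, timelapse_meta, 5,
                                              (5.0, 5.0), seed=45)
        free = simulate_free_tracks(0.44, timelapse_meta, 30, seed=46)
        mixed = TrackSet(free.tracks + [
            Track(100 + t.track_id, t.frame, t.t_s, t.x_um, t.y_um)
            for t in tracks], timelapse_meta)
        fit = fit_mobility_mixture(step_size_distribution(mixed, 1), 0.1)
        _, dwells = classify_bound_segments(mixed, fit, 3)
        long_events = dwells.durations > 50
        assert long_events.any()
        assert dwells.censored[long_events].all()


class TestRoundTripInvariant:
    def test_render_detect_link_recovers_tracks(self):
        # high-SNR, well-separated slow emitters: >= 99% of ground-truth
        # samples recovered, no spurious track outliving 3 frames
        meta = AcquisitionMeta(0.5, 0.5, field_size=(96, 96), n_frames=100)
        rng = np.random.default_rng(47)
        tracks = []
        starts = [(2.0, 2.0), (5.0, 2.5), (8.0, 2.0), (3.5, 7.0), (6.5, 7.5)]
        for i, (x0, y0) in enumerate(starts):
            xy = np.cumsum(rng.normal(0, np.sqrt(2 * 0.005 * 0.5),
                                      size=(100, 2)), axis=0) + [x0, y0]
            tracks.append(Track(i, np.arange(100), np.arange(100) * 0.5,
                                xy[:, 0], xy[:, 1]))
        truth = TrackSet(tracks, meta)
        stack = render_frames(truth, None, psf_sigma=0.084,
                              photons_per_frame=3000, substeps=5,
                              noise=CameraNoise(100.0, 2.0), seed=48)
        locs = detect_stack(stack, band_low=0.8, band_high=2.0,
                            intensity_min=100.0)
        linked = link_tracks(locs, meta, max_disp=0.5, max_gap=1)
        n_truth = 5 * 100
        recovered = 0
        for tr in truth:
            for i, f in enumerate(tr.frame):
                hits = [1 for L in locs[f]
                        if np.hypot(L.x_um - tr.x_um[i],
                                    L.y_um - tr.y_um[i]) < 0.2]
                recovered += bool(hits)
        assert recovered / n_truth >= 0.99
        spurious = [t for t in linked if len(t) > 3]
        assert len(spurious) == 5

    def test_rate_doubling_is_not_identifiable_from_steps(self):
        # (k_bind, k_off) and (2k_bind, 2k_off) give the same expected
        # occupancy; at matched occupancy the step-size distributions are
        # statistically indistinguishable, so steps alone cannot resolve
        # the absolute rate scale
        def labeled_steps(ts, gt):
            bound, free = [], []
            for tr in ts:
                lbl = gt.labels[tr.track_id]
                dr = np.hypot(np.diff(tr.x_um), np.diff(tr.y_um))
                for i in range(len(dr)):
                    dest = bound if lbl[tr.frame[i]] == BOUND else free
                    dest.append(dr[i])
            return np.array(bound), np.array(free)

        meta = AcquisitionMeta(0.1, 0.05, field_size=(200, 200),
                               n_frames=600)
        a = SimKineticParams(k_off=0.05, k_bl=0.0, k_bind=0.05)
        b = SimKineticParams(k_off=0.10, k_bl=0.0, k_bind=0.10)
        ta, ga = simulate_two_state_tracks(a, meta, 60, (10.0, 10.0),
                                           seed=49)
        tb, gb = simulate_two_state_tracks(b, meta, 60, (10.0, 10.0),
                                           seed=1049)
        ab, af = labeled_steps(ta, ga)
        bb, bf = labeled_steps(tb, gb)
        rng = np.random.default_rng(49)
        n = 4000
        sa = np.concatenate([rng.choice(ab, n // 2), rng.choice(af, n // 2)])
        sb = np.concatenate([rng.choice(bb, n // 2), rng.choice(bf, n // 2)])
        assert stats.ks_2samp(sa, sb).pvalue > 0.01
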