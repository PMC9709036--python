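"""Behavioral physiology: micro-movement detection, breathing extraction
through tracking and PCA, optical flow, event phase statistics, and
co-occurrence of movement sources."""

import numpy as np
import pytest
from scipy import stats

from agamasleep import behavior as B
from agamasleep.cycles import CycleSet
from agamasleep.synth import GenConfig, _texture, generate_recording
from conftest import circ_diff


def _cycles(n=60, period=90.0, sws_frac=0.55):
    starts = period * np.arange(n + 1)
    return CycleSet(starts, starts[:-1] + (1 - sws_frac) * period,
                    np.diff(starts), np.ones(n, bool))


class TestMovement:
    def test_pure_noise_event_rate_bounded(self, rng):
        accel = rng.standard_normal((3, 250 * 1200))
        mov = B.movement_detect(accel, 250.0)
        assert len(mov) / 20.0 <= 1.0   # events per minute

    def test_injected_twitches_all_found(self, rng):
        fs = 250.0
        accel = rng.standard_normal((3, int(fs * 600)))
        times = np.arange(10.0, 590.0, 10.0)
        # oscillatory transient: a unipolar bump would lift both envelopes
        # equally and leave the spread unchanged
        tt = np.arange(0, 0.25, 1 / fs)
        kern = np.exp(-tt / 0.05) * np.sin(2 * np.pi * 12 * tt)
        for t in times:
            i = int(t * fs)
            accel[:, i: i + len(kern)] += 10 * kern
        mov = B.movement_detect(accel, fs)
        hits = sum(1 for t in times if np.min(np.abs(mov.times_s - t)) <= 0.1)
        assert hits == len(times)

    def test_zero_signal_zero_events(self):
        mov = B.movement_detect(np.zeros((3, 250 * 60)), 250.0)
        assert len(mov) == 0

    def test_profile_conserves_amplitude(self, rng):
        ev = B.MovementEvents(np.sort(rng.uniform(0, 7200, 40)),
                              rng.uniform(1, 5, 40), 1.0, 0.1)
        t, prof = B.movement_profile(ev, 7200.0)
        assert prof.sum() == pytest.approx(ev.amplitude.sum())
        ev1 = B.MovementEvents(np.full(5, 100.0), np.ones(5), 1.0, 0.1)
        _, prof1 = B.movement_profile(ev1, 7200.0)
        assert prof1[0] == 5 and np.all(prof1[1:] == 0)


class TestTracking:
    def _frames(self, rng, n=60, shape=(64, 64), vel=(1.0, 0.0)):
        from scipy.ndimage import map_coordinates
        tex = _texture((shape[0] * 2, shape[1] * 2), rng, contrast=40)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        frames = []
        for i in range(n):
            f = 100 + map_coordinates(tex, [yy + 20 - vel[1] * i,
                                            xx + 20 - vel[0] * i], order=1)
            frames.append(np.clip(f, 0, 255).astype(np.uint8))
        return np.stack(frames)

    def test_translation_velocity_recovered(self, rng):
        frames = self._frames(rng, vel=(1.0, 0.0))
        tracks = B.track_rectangle(frames, (16, 16, 32, 32), fps=10.0)
        pos = np.nanmean(tracks.positions, axis=1)
        steps = np.diff(pos[:10, 0])
        assert np.median(steps) == pytest.approx(1.0, abs=0.2)

    def test_blank_frames_rejected(self):
        frames = np.full((5, 64, 64), 128, np.uint8)
        with pytest.raises(ValueError, match="corners"):
            B.track_rectangle(frames, (16, 16, 32, 32), fps=10.0)

    def test_scheduled_redetection_reported(self, rng):
        frames = self._frames(rng, n=50, vel=(0.0, 0.0))
        tracks = B.track_rectangle(frames, (16, 16, 32, 32), fps=10.0,
                                   redetect_every_s=2.0)
        assert len(tracks.redetect_frames) >= 3

    def test_lk_agrees_with_skimage_dense_flow(self, rng):
        from skimage.registration import optical_flow_ilk
        frames = self._frames(rng, n=2, vel=(0.8, 0.5))
        v, u = optical_flow_ilk(frames[0], frames[1])
        pts = B._detect_corners(frames[0], (16, 16, 32, 32), 40)
        new, valid = B._lk_track_points(frames[0], frames[1], pts)
        ours = np.median(new[valid] - pts[valid], axis=0)
        theirs = (np.median(u[16:48, 16:48]), np.median(v[16:48, 16:48]))
        # both should report the imposed (negative of sampling) shift
        assert ours[0] == pytest.approx(theirs[0], abs=0.3)
        assert ours[1] == pytest.approx(theirs[1], abs=0.3)


class TestBreathingTrace:
    def _tracks(self, disp, n_pts=30, fps=10.0, rng=None):
        base = rng.uniform(10, 50, (n_pts, 2))
        pos = base[None, :, :] + np.zeros((len(disp), n_pts, 2))
        pos[:, :, 1] += disp[:, None]
        return B.PointTracks(pos, fps, np.array([0]))

    def test_rigid_translation_recovered(self, rng):
        t = np.arange(600) / 10.0
        disp = 3 * np.sin(2 * np.pi * 0.1 * t)
        tracks = self._tracks(disp, rng=rng)
        res = B.breathing_trace(tracks)
        c = np.corrcoef(res.trace, disp)[0, 1]
        assert abs(c) >= 0.99
        assert res.pc1_explained >= 0.9

    def test_static_points_rejected(self, rng):
        tracks = self._tracks(np.zeros(100), rng=rng)
        with pytest.raises(ValueError, match="variance"):
            B.breathing_trace(tracks)


class TestBreathingRate:
    def test_constant_rate_sine(self):
        fs = 10.0
        t = np.arange(0, 300, 1 / fs)
        res = B.breathing_rate(np.sin(2 * np.pi * 0.5 * t), fs,
                               peak_lo_s=1.5)
        ok = ~res.rejected
        assert np.allclose(res.rates_hz[ok], 0.5, atol=0.03)

    def test_white_noise_mostly_rejected(self, rng):
        res = B.breathing_rate(rng.standard_normal(3000), 10.0)
        assert res.rejected.mean() >= 0.5

    def test_state_modulated_contrast_through_chain(self):
        # REM breathing faster and larger; direct displacement route with
        # long cycles so 24-s windows fit inside single states
        cfg = GenConfig(duration_s=2000, lfp_rate_hz=1000, temperature_c=19,
                        seed=8, period_cv=0.05)
        rec, truth = generate_recording(cfg)
        tr = rec.breath_displacement[::50]   # 10 Hz
        res = B.breathing_rate(tr, 10.0)
        st = truth.state_at(res.times_s)
        half = 12.0
        pure = np.array([
            lab if (truth.state_at([c - half])[0] == lab ==
                    truth.state_at([c + half])[0]) else ""
            for c, lab in zip(res.times_s, st)])
        ok = ~res.rejected & np.isfinite(res.rates_hz)
        r_rem = res.rates_hz[ok & (pure == "REM")]
        r_sws = res.rates_hz[ok & (pure == "SWS")]
        a_rem = res.amplitudes[ok & (pure == "REM")]
        a_sws = res.amplitudes[ok & (pure == "SWS")]
        ratio = np.median(r_rem) / np.median(r_sws)
        assert ratio == pytest.approx(cfg.breath_rate_rem_hz /
                                      cfg.breath_rate_sws_hz, rel=0.1)
        assert stats.ttest_ind(r_rem, r_sws).pvalue < 0.01
        assert stats.ttest_ind(a_rem, a_sws).pvalue < 0.01
        assert np.median(a_rem) > np.median(a_sws)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            B.breathing_rate(np.zeros(1000), 10.0)


class TestEyeFlow:
    def _eye_frames(self, rng, n=40, shift_at=(), shift_px=3.0, gain=None):
        from scipy.ndimage import map_coordinates
        tex = _texture((60, 60), rng, contrast=40)
        yy, xx = np.mgrid[0:48, 0:48].astype(float)
        off = 0.0
        frames = []
        for i in range(n):
            if i in shift_at:
                off += shift_px
            f = 100 + map_coordinates(tex, [yy + 6, xx + 6 + off], order=1)
            if gain is not None and i >= gain[0]:
                f = f + gain[1]
            frames.append(np.clip(f, 0, 255).astype(np.uint8))
        return np.stack(frames)

    def test_static_eye_flow_near_zero(self, rng):
        frames = self._eye_frames(rng)
        flow = B.eye_flow(frames, (8, 8, 32, 32))
        assert np.median(flow.magnitude[1:]) < 0.05

    def test_shift_produces_flow_spike(self, rng):
        frames = self._eye_frames(rng, shift_at=(20,))
        flow = B.eye_flow(frames, (8, 8, 32, 32))
        assert np.argmax(flow.magnitude) == 20
        assert flow.magnitude[20] > 10 * np.median(flow.magnitude[1:])

    def test_illumination_change_less_than_shift(self, rng):
        shifted = B.eye_flow(self._eye_frames(rng, shift_at=(20,)),
                             (8, 8, 32, 32)).magnitude[20]
        lit = B.eye_flow(self._eye_frames(rng, gain=(20, 10.0)),
                         (8, 8, 32, 32)).magnitude[20]
        assert lit < shifted


class TestEyeEvents:
    def test_noise_rate_bounded_by_mad_tail(self, rng):
        mag = np.abs(rng.standard_normal(6000))
        flow = B.EyeFlowSeries(np.arange(6000) / 5.0, mag, 5.0)
        ev, _ = B.eye_events(flow)
        # threshold = median + 6 MAD of |N(0,1)|; compare the observed
        # event rate with twice the analytic tail rate at that level
        med = np.median(mag)
        mad = np.median(np.abs(mag - med))
        thr = med + 6 * mad
        tail = 2 * (1 - stats.norm.cdf(thr))
        assert len(ev) / 1200.0 <= 2 * tail * 5.0

    def test_large_spikes_all_detected(self, rng):
        mag = np.abs(rng.standard_normal(6000))
        idx = np.arange(300, 5700, 300)
        mag[idx] = 20 * 1.48 * np.median(np.abs(mag - np.median(mag)))
        flow = B.EyeFlowSeries(np.arange(6000) / 5.0, mag, 5.0)
        ev, _ = B.eye_events(flow)
        assert all(np.min(np.abs(ev - i / 5.0)) < 0.3 for i in idx)

    def test_surrogate_preserves_per_cycle_counts(self, rng):
        cycles = _cycles(20)
        times = np.sort(rng.uniform(0, cycles.rem_onsets_s[-1], 100))
        surr = B.shuffle_events_in_cycles(times, cycles, rng)
        for i in range(20):
            r0, r1 = cycles.rem_onsets_s[i], cycles.rem_onsets_s[i + 1]
            n_orig = np.sum((times >= r0) & (times < r1))
            n_surr = np.sum((surr >= r0) & (surr < r1))
            assert n_orig == n_surr


class TestEventPhaseStats:
    def test_von_mises_events_recovered(self, rng):
        cycles = _cycles(100)
        phases = rng.vonmises(np.pi, 6.0, 500) % (2 * np.pi)
        idx = rng.integers(0, 100, 500)
        times = cycles.rem_onsets_s[idx] + phases / (2 * np.pi) * 90.0
        ps = B.event_phase_stats(times, cycles)
        assert abs(circ_diff(ps.mean_phase_rad, np.pi)) < 0.15
        assert ps.rayleigh_p < 0.01

    def test_uniform_events_not_significant(self, rng):
        cycles = _cycles(100)
        times = np.sort(rng.uniform(0, cycles.rem_onsets_s[-1], 400))
        ps = B.event_phase_stats(times, cycles)
        assert ps.rayleigh_p > 0.05

    def test_repeated_single_phase(self):
        cycles = _cycles(30)
        times = cycles.rem_onsets_s[:-1] + 0.25 * 90.0
        ps = B.event_phase_stats(times, cycles)
        assert abs(circ_diff(ps.mean_phase_rad, np.pi / 2)) < 1e-6
        assert ps.resultant_length == pytest.approx(1.0)

    def test_too_few_events_rejected(self):
        cycles = _cycles(30)
        with pytest.raises(ValueError):
            B.event_phase_stats(cycles.rem_onsets_s[:5] + 10.0, cycles)


class TestCooccurrence:
    def test_identical_sets_full_overlap(self, rng):
        t = np.sort(rng.uniform(0, 1000, 50))
        out = B.cooccurrence(t, t, tol_s=1.0)
        assert out["frac_a_near_b"] == 1.0
        assert out["frac_b_near_a"] == 1.0

    def test_independent_poisson_coincidence_rate(self, rng):
        dur = 8 * 3600.0
        a = np.sort(rng.uniform(0, dur, rng.poisson(0.02 * dur)))
        b = np.sort(rng.uniform(0, dur, rng.poisson(0.02 * dur)))
        out = B.cooccurrence(a, b, tol_s=1.0)
        expected = 1 - np.exp(-2 * 0.02 * 1.0)
        assert out["frac_a_near_b"] == pytest.approx(expected, abs=0.03)

    def test_independent_traces_low_xcorr(self, rng):
        n = 40000
        out = B.cooccurrence([], [], trace_a=rng.standard_normal(n),
                             trace_b=rng.standard_normal(n), trace_fs=10.0)
        assert out["max_xcorr"] < 3 / np.sqrt(n)

    def test_empty_series_flagged(self):
        out = B.cooccurrence([], [1.0, 2.0])
        assert out["empty"] and out["frac_a_near_b"] == 0.0
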