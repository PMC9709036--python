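"""Sharp-wave detection and characterization: template building, the
whitened matched filter, threshold optimization, state-resolved rates,
morphology, and ripple analysis."""

import numpy as np
import pytest
from scipy import signal

from agamasleep import shw as shw_mod
from agamasleep.cycles import CycleSet
from agamasleep.shw import (ShwEvents, ShwTemplate, build_template, detect_shw,
                            night_quality_filter, optimize_threshold,
                            resample_for_detection, ripple_analysis,
                            score_series, shw_morphology, shw_rate_dynamics,
                            zscore_by_group)
from agamasleep.spectral import LfpSignal
from agamasleep.synth import shw_waveform
from conftest import match_f1

FS = 400.0


def _colored_background(rng, dur_s, delta_rms=120.0, white_sd=20.0):
    n = int(dur_s * FS)
    sos = signal.butter(4, 4, "lowpass", fs=FS, output="sos")
    d = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return d * delta_rms / d.std() + white_sd * rng.standard_normal(n)


def _inject(x, kernel, times):
    half = len(kernel) // 2
    for t in times:
        i = int(round(t * FS))
        x[i - half: i - half + len(kernel)] += kernel
    return x


class TestTemplate:
    def test_identical_copies_reproduce_waveform(self):
        w = shw_waveform(120, FS)
        tmpl = build_template([3 * w] * 5)
        assert np.allclose(tmpl.waveform, w / np.abs(w).max(), atol=1e-9)
        assert np.abs(tmpl.waveform).max() == pytest.approx(1.0)
        assert tmpl.waveform.mean() == pytest.approx(0.0, abs=1e-12)

    def test_jittered_copies_broaden_template(self, rng):
        w = shw_waveform(120, FS)
        pad = np.zeros(20)
        segs = []
        for _ in range(200):
            shift = rng.integers(-4, 5)  # +/-10 ms at 400 Hz
            segs.append(np.roll(np.concatenate([pad, w, pad]), shift))
        tmpl = build_template(segs)

        def eff_width(v):
            # area/peak: strictly grows when shifted copies are averaged
            mag = np.abs(v)
            return mag.sum() / mag.max()

        padded = np.concatenate([pad, w, pad])
        assert eff_width(tmpl.waveform) > eff_width(padded / np.abs(padded).max())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_template([])


class TestDetection:
    def test_injected_events_perfectly_recovered(self, rng):
        x = _colored_background(rng, 400)
        amp = 10 * x.std()
        kern = amp * shw_waveform(120, FS)
        times = np.sort(rng.uniform(5, 395, 50))
        times = times[np.concatenate([[True], np.diff(times) > 0.5])]
        _inject(x, kern, times)
        tmpl = ShwTemplate(shw_waveform(120, FS))
        ev = detect_shw(LfpSignal(x, FS), tmpl, height=0.4, ref_amp_uv=amp,
                        artifact_uv=1e9)
        f1, prec, rec = match_f1(ev.times_s, times)
        assert prec == 1.0 and rec == 1.0

    def test_flat_signal_no_events(self):
        tmpl = ShwTemplate(shw_waveform(120, FS))
        ev = detect_shw(LfpSignal(np.zeros(int(60 * FS)), FS), tmpl)
        assert len(ev) == 0

    def test_artifact_amplitude_excluded(self, rng):
        x = _colored_background(rng, 120)
        kern = shw_waveform(120, FS)
        _inject(x, 2000 * kern, [40.0])   # artifact-sized
        _inject(x, 600 * kern, [80.0])    # legitimate event
        tmpl = ShwTemplate(shw_waveform(120, FS))
        ev = detect_shw(LfpSignal(x, FS), tmpl, height=0.4, ref_amp_uv=600,
                        artifact_uv=1000)
        assert any(abs(t - 80) < 0.05 for t in ev.times_s)
        assert not any(abs(t - 40) < 0.05 for t in ev.times_s)

    def test_template_longer_than_signal_rejected(self):
        tmpl = ShwTemplate(shw_waveform(120, FS))
        with pytest.raises(ValueError):
            score_series(LfpSignal(np.zeros(10), FS), tmpl)

    def test_threshold_monotonicity(self, rng):
        x = _colored_background(rng, 200)
        _inject(x, 500 * shw_waveform(120, FS),
                np.arange(5.0, 195.0, 4.0))
        tmpl = ShwTemplate(shw_waveform(120, FS))
        sig = LfpSignal(x, FS)
        counts = [len(detect_shw(sig, tmpl, height=h, ref_amp_uv=500,
                                 artifact_uv=1e9))
                  for h in np.linspace(0.05, 2.0, 25)]
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))


class TestThresholdOptimization:
    def test_separable_scores_perfect_f1(self, rng):
        scores = np.concatenate([rng.uniform(0, 0.3, 200),
                                 rng.uniform(0.6, 1.0, 50)])
        labels = np.concatenate([np.zeros(200, bool), np.ones(50, bool)])
        thr, f1 = optimize_threshold(scores, labels)
        assert f1 == 1.0 and 0.3 < thr <= 0.6

    def test_single_positive_above_negatives(self):
        scores = np.array([0.1, 0.2, 0.3, 0.9])
        labels = np.array([False, False, False, True])
        thr, f1 = optimize_threshold(scores, labels)
        assert f1 == 1.0 and 0.3 < thr <= 0.9

    def test_random_labels_f1_near_prevalence(self, rng):
        scores = rng.uniform(0, 1, 2000)
        labels = rng.uniform(0, 1, 2000) < 0.2
        _, f1 = optimize_threshold(scores, labels)
        # the optimum of a label-independent score is to accept ~everything:
        # F1 -> 2p/(1+p) for prevalence p
        assert f1 == pytest.approx(2 * 0.2 / 1.2, abs=0.05)

    def test_label_validation(self):
        with pytest.raises(ValueError):
            optimize_threshold([1.0, 2.0], [False, False])
        with pytest.raises(ValueError):
            optimize_threshold([1.0, 2.0], [True, True])


class TestRateDynamics:
    def _cycles(self, n=300, period=90.0, sws_frac=0.55):
        starts = period * np.arange(n + 1)
        rem_len = (1 - sws_frac) * period
        return CycleSet(starts, starts[:-1] + rem_len, np.diff(starts),
                        np.ones(n, bool))

    def test_sws_restricted_events_contrast(self, rng):
        cycles = self._cycles()
        # events only in the SWS stretch of each cycle
        times = np.concatenate([
            rng.uniform(s + 40.5, s + 90, 8)
            for s in cycles.rem_onsets_s[:-1]])
        ev = ShwEvents(np.sort(times), np.ones(len(times)),
                       np.ones(len(times)))
        out = shw_rate_dynamics(ev, cycles)
        ratio = out["sws_norm_rates"].mean() / max(out["rem_norm_rates"].mean(),
                                                   1e-9)
        assert ratio > 5
        assert out["p_value"] < 0.001

    def test_uniform_events_not_significant(self, rng):
        cycles = self._cycles()
        times = np.sort(rng.uniform(0, cycles.rem_onsets_s[-1], 2400))
        ev = ShwEvents(times, np.ones(len(times)), np.ones(len(times)))
        out = shw_rate_dynamics(ev, cycles)
        assert out["p_value"] > 0.05

    def test_rate_histogram_conserves_counts(self, rng):
        cycles = self._cycles(20)
        times = np.sort(rng.uniform(0, 1800, 500))
        ev = ShwEvents(times, np.ones(500), np.ones(500))
        out = shw_rate_dynamics(ev, cycles, bin_s=1.2, t_end=1800.0)
        assert np.sum(out["rate_hz"]) * 1.2 == pytest.approx(500)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            shw_rate_dynamics(ShwEvents(np.array([]), np.array([]),
                                        np.array([])), self._cycles())


class TestMorphology:
    def test_fwhm_recovered_for_gaussian_transient(self):
        fs = FS
        x = np.zeros(int(120 * fs))
        sigma = 0.120 / 2.355  # 120-ms FWHM
        tt = np.arange(-1, 1, 1 / fs)
        pulse = 300 * np.exp(-tt ** 2 / (2 * sigma ** 2))
        times = np.arange(10.0, 110.0, 5.0)
        for t in times:
            i = int(t * fs) - len(pulse) // 2
            x[i: i + len(pulse)] += pulse
        ev = ShwEvents(times, np.ones(len(times)), np.full(len(times), 300.0))
        ev2, wave, lags = shw_morphology(LfpSignal(x, fs), ev)
        assert np.median(ev2.width_ms) == pytest.approx(120, abs=10)
        assert np.median(ev2.amp_uv) == pytest.approx(300, rel=0.05)

    def test_amplitude_scales_width_constant(self):
        fs = FS
        sigma = 0.120 / 2.355
        tt = np.arange(-1, 1, 1 / fs)
        pulse = np.exp(-tt ** 2 / (2 * sigma ** 2))
        times = np.arange(10.0, 110.0, 5.0)

        def measure(amp):
            x = np.zeros(int(120 * fs))
            for t in times:
                i = int(t * fs) - len(pulse) // 2
                x[i: i + len(pulse)] += amp * pulse
            ev = ShwEvents(times, np.ones(len(times)), np.ones(len(times)))
            ev2, _, _ = shw_morphology(LfpSignal(x, fs), ev)
            return np.median(ev2.amp_uv), np.median(ev2.width_ms)

        a1, w1 = measure(200.0)
        a2, w2 = measure(400.0)
        assert a2 / a1 == pytest.approx(2.0, rel=0.02)
        assert w2 == pytest.approx(w1, rel=0.05)

    def test_edge_events_skipped(self):
        x = np.zeros(int(10 * FS))
        ev = ShwEvents(np.array([0.01, 5.0]), np.ones(2), np.ones(2))
        x[int(5 * FS)] = 100.0
        ev2, _, _ = shw_morphology(LfpSignal(x, FS), ev)
        assert len(ev2) == 1

    def test_zscore_by_group(self, rng):
        vals = rng.normal(100, 20, 60)
        groups = np.repeat(["a", "b", "c"], 20)
        z = zscore_by_group(vals, groups)
        for g in "abc":
            assert z[groups == g].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[groups == g].std() == pytest.approx(1.0, abs=1e-9)


class TestRipples:
    def _trace_with_ripples(self, rng, with_ripple=True, fs=1000.0):
        n = int(300 * fs)
        sos = signal.butter(4, 4, "lowpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(n))
        x *= 100 / x.std()
        x += 5.0 * rng.standard_normal(n)   # broadband floor
        times = np.arange(5.0, 295.0, 3.0)
        kern = -400 * np.exp(-np.arange(-0.5, 0.5, 1 / fs) ** 2 / (2 * 0.05 ** 2))
        burst_t = np.arange(-0.2, 0.2, 1 / fs)
        burst = (60 * np.exp(-burst_t ** 2 / (2 * 0.02 ** 2)) *
                 np.sin(2 * np.pi * 100 * burst_t))
        for t in times:
            i = int(t * fs)
            x[i - len(kern) // 2: i + len(kern) // 2] += kern
            if with_ripple:
                x[i - len(burst) // 2: i + len(burst) // 2] += burst
        ev = ShwEvents(times, np.ones(len(times)), np.ones(len(times)))
        return LfpSignal(x, fs), ev

    def test_triggered_envelope_peaks_at_trough(self, rng):
        sig, ev = self._trace_with_ripples(rng, True)
        out = ripple_analysis(sig, ev)
        peak_lag = out["trigger_lags_s"][np.argmax(out["triggered_envelope"])]
        assert abs(peak_lag) <= 0.02
        assert out["spectrogram"] is not None

    def test_no_ripple_content_flat_envelope(self, rng):
        sig, ev = self._trace_with_ripples(rng, False)
        out = ripple_analysis(sig, ev)
        env = out["triggered_envelope"]
        assert env.max() / np.median(env) < 1.5

    def test_zero_signal_zero_envelope(self):
        sig = LfpSignal(np.zeros(int(10 * 1000)), 1000.0)
        ev = ShwEvents(np.array([5.0]), np.ones(1), np.ones(1))
        out = ripple_analysis(sig, ev)
        assert np.allclose(out["envelope"], 0.0)

    def test_band_above_nyquist_rejected(self):
        sig = LfpSignal(np.zeros(4000), 400.0)
        ev = ShwEvents(np.array([5.0]), np.ones(1), np.ones(1))
        with pytest.raises(ValueError, match="Nyquist"):
            ripple_analysis(sig, ev)


class TestQualityFilter:
    @pytest.mark.parametrize("p2v, power, expected", [
        (0.19, 50.0, False),   # weak oscillation
        (0.5, 45.0, True),
        (0.2, 45.0, True),     # boundary included
        (0.5, 39.0, False),    # low power
    ])
    def test_inclusion_rules(self, p2v, power, expected):
        ok, reasons = night_quality_filter(p2v, power)
        assert ok is expected
        assert (len(reasons) == 0) is expected
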