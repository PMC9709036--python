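"""Sharp-wave (ShW) detection and characterization.

Detection is a whitened matched filter: the LFP is anti-alias filtered
and resampled to 400 Hz, spectrally whitened by its own Welch PSD, and
cross-correlated with the whitened event template.  The score series is
the resulting least-squares amplitude estimate divided by a reference
amplitude, so a clean template occurrence at the reference amplitude
scores 1 and the detection threshold is an amplitude fraction.  The
threshold can be recalibrated by F1 optimization on a labeled set.

Morphology (FWHM width, amplitude), state-resolved rates, and
ripple-band (60-200 Hz) envelope analysis round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import signal, stats

from .spectral import LfpSignal
from .cycles import CycleSet, phase_average

__all__ = [
    "ShwTemplate",
    "ShwEvents",
    "build_template",
    "resample_for_detection",
    "score_series",
    "detect_shw",
    "optimize_threshold",
    "shw_rate_dynamics",
    "shw_morphology",
    "ripple_analysis",
    "night_quality_filter",
    "zscore_by_group",
]

log = logging.getLogger(__name__)

DETECT_RATE_HZ = 400.0


@dataclass
class ShwTemplate:
    waveform: np.ndarray   # at 400 Hz, zero mean, peak |value| = 1
    rate_hz: float = DETECT_RATE_HZ

    @property
    def length_ms(self) -> float:
        return 1000.0 * len(self.waveform) / self.rate_hz


@dataclass
class ShwEvents:
    times_s: np.ndarray
    score: np.ndarray
    amp_uv: np.ndarray
    width_ms: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.times_s)


def build_template(curated_segments, in_rate_hz: float = DETECT_RATE_HZ) -> ShwTemplate:
    """Average curated event snippets into a unit-peak, zero-mean template."""
    segs = [np.asarray(s, float) for s in curated_segments]
    if len(segs) == 0:
        raise ValueError("no curated segments supplied")
    if in_rate_hz != DETECT_RATE_HZ:
        n_out = int(round(len(segs[0]) * DETECT_RATE_HZ / in_rate_hz))
        segs = [signal.resample(s, n_out) for s in segs]
    if len({len(s) for s in segs}) != 1:
        raise ValueError("curated segments must share a common length")
    w = np.mean(segs, axis=0)
    w = w - w.mean()
    peak = np.abs(w).max()
    if peak == 0:
        raise ValueError("template is identically zero")
    return ShwTemplate(w / peak)


def resample_for_detection(sig: LfpSignal, anti_alias_hz: float = 160.0) -> LfpSignal:
    """Anti-alias low-pass then resample to the 400-Hz detection rate."""
    if sig.rate < DETECT_RATE_HZ:
        raise ValueError("LFP rate below the 400-Hz detection rate")
    sos = signal.butter(4, anti_alias_hz, "lowpass", fs=sig.rate, output="sos")
    x = signal.sosfiltfilt(sos, sig.samples)
    n_out = int(round(len(x) * DETECT_RATE_HZ / sig.rate))
    y = signal.resample(x, n_out)
    return LfpSignal(y, DETECT_RATE_HZ, sig.t0)


def score_series(sig400: LfpSignal, template: ShwTemplate,
                 ref_amp_uv: float = 400.0) -> np.ndarray:
    """Whitened matched-filter amplitude estimate over the trace.

    The trace and template are whitened by the trace's own Welch PSD; the
    correlation is normalized by the whitened template energy, giving a
    per-sample least-squares estimate of event amplitude, expressed as a
    fraction of ``ref_amp_uv``.
    """
    x = sig400.samples
    w = template.waveform
    n = len(x)
    if len(w) > n:
        raise ValueError("template longer than signal")
    f, pxx = signal.welch(x, fs=sig400.rate, nperseg=min(4096, n))
    if np.max(pxx) <= 0:      # flat trace: nothing to detect
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / sig400.rate)
    s_f = np.maximum(np.interp(freqs, f, pxx), np.max(pxx) * 1e-8)
    xf = np.fft.rfft(x)
    wp = np.zeros(n)
    wp[: len(w)] = w
    wp = np.roll(wp, -(len(w) // 2))
    wf = np.fft.rfft(wp)
    num = np.fft.irfft(xf * np.conj(wf) / s_f, n)
    den = np.fft.irfft(np.abs(wf) ** 2 / s_f, n)[0]
    score = num / (den * ref_amp_uv)
    # the circular FFT correlation wraps around the record ends; blank one
    # template length at each edge
    score[: len(w)] = 0.0
    score[-len(w):] = 0.0
    return score


def detect_shw(sig: LfpSignal, template: ShwTemplate, height: float = 0.25,
               artifact_uv: float = 1000.0, ref_amp_uv: float = 400.0,
               refractory_s: float = 0.1) -> ShwEvents:
    """Matched-filter ShW detection on the 400-Hz trace.

    Score peaks at least ``height`` (with a 100-ms refractory) become
    events; the event amplitude is the peak deviation from the local
    median baseline on the 400-Hz trace, and events beyond the artifact
    ceiling are dropped.
    """
    sig400 = sig if sig.rate == DETECT_RATE_HZ else resample_for_detection(sig)
    sc = score_series(sig400, template, ref_amp_uv)
    dist = max(int(round(refractory_s * sig400.rate)), 1)
    peaks, props = signal.find_peaks(sc, height=height, distance=dist)
    amps = np.array([_event_amplitude(sig400.samples, p, sig400.rate)
                     for p in peaks])
    if len(peaks):
        keep = np.abs(amps) <= artifact_uv
        peaks, amps = peaks[keep], amps[keep]
        scores = props["peak_heights"][keep]
    else:
        scores = np.array([])
    return ShwEvents(peaks / sig400.rate + sig400.t0, scores, amps)


def _event_amplitude(x, idx, fs, half_s: float = 0.25):
    half = int(half_s * fs)
    lo, hi = max(idx - half, 0), min(idx + half, len(x))
    seg = x[lo:hi]
    base = np.median(seg)
    return seg[np.argmax(np.abs(seg - base))] - base


def optimize_threshold(scores, labels, grid_size: int = 1000):
    """F1-optimal score threshold over a labeled candidate set.

    ``labels`` marks true events among score candidates.  The grid spans
    the observed score range; ties resolve to the higher threshold.
    Returns ``(threshold, best_f1)``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if not labels.any():
        raise ValueError("need at least one positive label")
    if labels.all():
        raise ValueError("need at least one negative label")
    grid = np.linspace(scores.min(), scores.max(), grid_size)
    best_f1, best_thr = -1.0, grid[0]
    npos = labels.sum()
    for thr in grid:
        pred = scores >= thr
        tp = np.sum(pred & labels)
        fp = np.sum(pred & ~labels)
        denom = 2 * tp + fp + (npos - tp)
        f1 = 2 * tp / denom if denom else 0.0
        if f1 >= best_f1:   # >= keeps the higher threshold on ties
            best_f1, best_thr = f1, thr
    return float(best_thr), float(best_f1)


def shw_rate_dynamics(events: ShwEvents, cycles: CycleSet, bin_s: float = 1.2,
                      t_end: float | None = None):
    """Binned ShW rate, per-cycle state-normalized rates, and state contrast.

    Per kept cycle the SWS and REM segment rates are normalized by the
    cycle's mean rate; a paired t-test across cycles quantifies the state
    difference; the phase-average curve comes from the cycle-phase
    machinery.  Returns a dict.
    """
    if len(events) == 0:
        raise ValueError("no events")
    t_end = events.times_s.max() + bin_s if t_end is None else t_end
    edges = np.arange(0, t_end + bin_s, bin_s)
    counts, _ = np.histogram(events.times_s, edges)
    rate = counts / bin_s
    centers = edges[:-1] + bin_s / 2

    sws_rates, rem_rates = [], []
    for i in np.nonzero(cycles.kept)[0]:
        r0, r1 = cycles.rem_onsets_s[i], cycles.rem_onsets_s[i + 1]
        s0 = cycles.sws_onsets_s[i]
        n_rem = np.sum((events.times_s >= r0) & (events.times_s < s0))
        n_sws = np.sum((events.times_s >= s0) & (events.times_s < r1))
        rem_r = n_rem / max(s0 - r0, 1e-9)
        sws_r = n_sws / max(r1 - s0, 1e-9)
        mean_r = (n_rem + n_sws) / (r1 - r0)
        if mean_r > 0:
            sws_rates.append(sws_r / mean_r)
            rem_rates.append(rem_r / mean_r)
    sws_rates, rem_rates = np.array(sws_rates), np.array(rem_rates)
    tt = stats.ttest_rel(sws_rates, rem_rates) if len(sws_rates) > 1 else None

    try:
        phases, curve, raw = phase_average(centers, rate, cycles)
    except ValueError:
        phases = curve = raw = None
    return {
        "rate_times_s": centers,
        "rate_hz": rate,
        "sws_norm_rates": sws_rates,
        "rem_norm_rates": rem_rates,
        "t_stat": tt.statistic if tt else np.nan,
        "p_value": tt.pvalue if tt else np.nan,
        "phase_bins_rad": phases,
        "phase_curve": curve,
        "phase_curve_raw": raw,
    }


def shw_morphology(sig: LfpSignal, events: ShwEvents, lowpass_hz: float = 40.0,
                   half_window_s: float = 0.5):
    """Per-event FWHM and amplitude on the low-passed trace, plus the mean
    waveform.

    The width is the full width at half maximum of the main deflection
    from the local median baseline; events too close to the trace edge
    are skipped (logged).  Returns ``(ShwEvents with widths, mean_waveform,
    waveform_lags_s)``.
    """
    if len(events) == 0:
        raise ValueError("no events")
    sos = signal.butter(4, lowpass_hz, "lowpass", fs=sig.rate, output="sos")
    x = signal.sosfiltfilt(sos, sig.samples)
    half = int(half_window_s * sig.rate)
    times, scores, amps, widths, snips = [], [], [], [], []
    skipped = 0
    for t, sc in zip(events.times_s, events.score):
        i = int(round((t - sig.t0) * sig.rate))
        if i - half < 0 or i + half >= len(x):
            skipped += 1
            continue
        seg = x[i - half: i + half]
        base = np.median(seg)
        dev = seg - base
        p = np.argmax(np.abs(dev))
        amp = dev[p]
        hm = abs(amp) / 2
        mag = np.abs(dev)
        left = p
        while left > 0 and mag[left] > hm:
            left -= 1
        right = p
        while right < len(mag) - 1 and mag[right] > hm:
            right += 1
        widths.append((right - left) / sig.rate * 1000.0)
        times.append(t)
        scores.append(sc)
        amps.append(amp)
        snips.append(dev)
    if skipped:
        log.info("shw_morphology: skipped %d edge events", skipped)
    if not times:
        raise ValueError("all events at trace edges")
    mean_wave = np.mean(snips, axis=0)
    lags = (np.arange(-half, half)) / sig.rate
    ev = ShwEvents(np.array(times), np.array(scores), np.array(amps),
                   np.array(widths))
    return ev, mean_wave, lags


def ripple_analysis(sig: LfpSignal, events: ShwEvents, band=(60.0, 200.0),
                    window_s: float = 0.25, max_events: int = 200,
                    cwt_freqs=None):
    """Ripple-band envelope and event-triggered Morlet spectrogram.

    The envelope is the Hilbert magnitude of the band-passed (Butterworth)
    trace; the triggered average is taken over up to ``max_events`` events.
    The wavelet frequencies default to 40-250 Hz, logarithmically spaced.
    Returns a dict.
    """
    if band[1] >= sig.rate / 2:
        raise ValueError("ripple band above Nyquist")
    sos = signal.butter(4, band, "bandpass", fs=sig.rate, output="sos")
    xb = signal.sosfiltfilt(sos, sig.samples)
    env = np.abs(signal.hilbert(xb))

    half = int(window_s * sig.rate)
    segs, raws = [], []
    for t in events.times_s[:max_events]:
        i = int(round((t - sig.t0) * sig.rate))
        if i - half < 0 or i + half >= len(env):
            continue
        segs.append(env[i - half: i + half])
        raws.append(sig.samples[i - half: i + half])
    lags = np.arange(-half, half) / sig.rate
    trig_env = np.mean(segs, axis=0) if segs else np.zeros(2 * half)

    spec = freqs = None
    if raws:
        import pywt
        if cwt_freqs is None:
            cwt_freqs = np.geomspace(40.0, 250.0, 32)
        fc = pywt.central_frequency("morl")
        scales = fc * sig.rate / cwt_freqs
        mean_raw = np.mean(raws, axis=0)
        coefs, freqs = pywt.cwt(mean_raw, scales, "morl",
                                sampling_period=1.0 / sig.rate)
        spec = np.abs(coefs)
    return {
        "envelope": env,
        "trigger_lags_s": lags,
        "triggered_envelope": trig_env,
        "spectrogram": spec,
        "spectrogram_freqs_hz": freqs,
        "n_events_used": len(segs),
    }


def night_quality_filter(p2v: float, power_db: float, p2v_min: float = 0.2,
                         power_min_db: float = 40.0):
    """Night inclusion flag with reasons.

    Boundary values are included (>= rule).  Returns ``(bool, reasons)``.
    """
    reasons = []
    if p2v < p2v_min:
        reasons.append(f"weak oscillation: P2V {p2v:.3f} < {p2v_min}")
    if power_db < power_min_db:
        reasons.append(f"low power: {power_db:.1f} dB < {power_min_db}")
    return len(reasons) == 0, reasons


def zscore_by_group(values, groups):
    """Z-score values within each group (per-animal pooling utility)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in np.unique(groups):
        m = groups == g
        sd = values[m].std(ddof=0)
        out[m] = (values[m] - values[m].mean()) / sd if sd > 0 else 0.0
    return out
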