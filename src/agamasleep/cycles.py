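"""Sleep-cycle machinery on the delta/beta series.

Autocorrelation period/P2V statistics, sliding sleep-interval detection,
Hilbert-phase segmentation into REM/SWS cycles, the cycle-phase clock used
by every phase-locking analysis, and the robust CV of cycle durations.

Conventions: the peak-to-valley statistic (P2V) is the first
autocorrelation peak minus the first valley minus twice the 95%
confidence bound 1.96/sqrt(N), floored at zero; cycle phase runs 0 -> 2pi
from one detected REM onset to the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal import medfilt
from scipy.ndimage import uniform_filter1d

from .spectral import DeltaBetaSeries

__all__ = [
    "AutocorrResult",
    "OscillationStats",
    "SleepInterval",
    "CycleSet",
    "autocorrelation",
    "global_oscillation_stats",
    "sliding_sleep_detection",
    "best_oscillation_window",
    "segment_cycles",
    "cycle_phase",
    "phase_average",
    "robust_cv",
]


@dataclass
class AutocorrResult:
    lags_s: np.ndarray
    ac: np.ndarray
    conf_bound: float   # 1.96 / sqrt(N)


@dataclass
class OscillationStats:
    period_s: float
    antiphase_lag_s: float
    p2v: float

    @property
    def has_oscillation(self) -> bool:
        return np.isfinite(self.period_s)


@dataclass
class SleepInterval:
    start_s: float
    end_s: float

    @property
    def empty(self) -> bool:
        return not self.end_s > self.start_s

    def duration_s(self) -> float:
        return max(self.end_s - self.start_s, 0.0)


@dataclass
class CycleSet:
    rem_onsets_s: np.ndarray   # n+1 onsets bound n cycles
    sws_onsets_s: np.ndarray   # one inside each cycle
    durations_s: np.ndarray    # successive REM-onset differences
    kept: np.ndarray           # False for cycles off 1.5x the mean duration

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_durations(self) -> np.ndarray:
        return self.durations_s[self.kept]


def autocorrelation(series, max_lag_s: float, step_s: float | None = None) -> AutocorrResult:
    """Biased normalized autocorrelation of a (demeaned) series.

    ``series`` is a DeltaBetaSeries or a plain array (then ``step_s``
    gives its sampling step, default 1 s).  The 95% confidence bound for
    a white-noise null is 1.96/sqrt(N).
    """
    if isinstance(series, DeltaBetaSeries):
        x = series.values
        step = series.step_s
    else:
        x = np.asarray(series, float)
        step = 1.0 if step_s is None else step_s
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2 or np.ptp(x) == 0:
        raise ValueError("autocorrelation needs a non-constant series")
    x = x - x.mean()
    nlag = min(int(round(max_lag_s / step)), n - 1)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(fx * np.conj(fx), nfft)[: nlag + 1]
    ac /= n * x.var()
    lags = np.arange(nlag + 1) * step
    return AutocorrResult(lags, ac, 1.96 / np.sqrt(n))


def _first_extrema(acr: AutocorrResult):
    """(peak_idx, valley_idx) of the first oscillatory extrema, or Nones.

    The first peak is the first local maximum after the autocorrelation's
    first zero-crossing (avoiding the shoulder at small lags); the first
    valley is the first local minimum after lag 0.  Extrema must have
    prominence at least the confidence bound to count.
    """
    ac = acr.ac
    zc = np.nonzero(np.diff(np.sign(ac)) < 0)[0]
    first_zc = zc[0] + 1 if len(zc) else None
    valleys, _ = signal.find_peaks(-ac, prominence=acr.conf_bound)
    peaks, _ = signal.find_peaks(ac, prominence=acr.conf_bound)
    if first_zc is not None:
        peaks = peaks[peaks > first_zc]
    else:
        peaks = np.array([], int)
    valley = valleys[0] if len(valleys) else None
    peak = None
    if len(peaks):
        if valley is not None:
            after = peaks[peaks > valley]
            peak = after[0] if len(after) else peaks[0]
        else:
            peak = peaks[0]
    return peak, valley


def global_oscillation_stats(acr: AutocorrResult) -> OscillationStats:
    """Oscillation period, anti-phase lag and P2V from an autocorrelation.

    Returns a "no oscillation" result (NaN period, P2V 0) when no
    qualifying peak/valley pair exists.
    """
    peak, valley = _first_extrema(acr)
    if peak is None or valley is None:
        return OscillationStats(np.nan, np.nan, 0.0)
    p2v = max(acr.ac[peak] - acr.ac[valley] - 2 * acr.conf_bound, 0.0)
    return OscillationStats(acr.lags_s[peak], acr.lags_s[valley], p2v)


def sliding_sleep_detection(db: DeltaBetaSeries, bin_s: float = 1000.0,
                            step_s: float = 100.0, smooth_s: float = 10.0,
                            p2v_thresh: float = 0.25,
                            medfilt_s: float = 3600.0, binarize: float = 0.5,
                            global_stats: OscillationStats | None = None):
    """Locate the consolidated sleep interval from a floating autocorrelation.

    A P2V is computed in each floating bin (autocorrelation smoothed by a
    ``smooth_s`` moving average, extrema searched within +/-20 s of the
    global period and anti-phase lag); bins with P2V above threshold are
    sleep; the boolean series is majority-filtered over ``medfilt_s`` and
    the longest run is returned.

    Returns ``(SleepInterval, bin_start_times, local_period_s, local_p2v)``.
    """
    step = db.step_s
    nbin = int(round(bin_s / step))
    nstep = int(round(step_s / step))
    x = db.values.copy()
    x[~np.isfinite(x)] = np.nanmedian(x[np.isfinite(x)])
    if len(x) < 2 * nbin:
        raise ValueError("record shorter than two floating bins")

    if global_stats is None:
        global_stats = global_oscillation_stats(
            autocorrelation(db, max_lag_s=min(600.0, len(x) * step / 3)))
    if not global_stats.has_oscillation:
        return SleepInterval(0.0, 0.0), np.array([]), np.array([]), np.array([])
    gp, gv = global_stats.period_s, global_stats.antiphase_lag_s

    starts = np.arange(0, len(x) - nbin + 1, nstep)
    t_bins = db.times_s[starts]
    periods = np.full(len(starts), np.nan)
    p2vs = np.zeros(len(starts))
    ksm = max(int(round(smooth_s / step)), 1)
    max_lag = min(2 * gp + 40, bin_s / 2)
    for k, s0 in enumerate(starts):
        seg = x[s0:s0 + nbin]
        if np.ptp(seg) == 0:
            continue
        acr = autocorrelation(seg, max_lag_s=max_lag, step_s=step)
        ac = uniform_filter1d(acr.ac, ksm)
        lags = acr.lags_s
        pk_m = (lags >= gp - 20) & (lags <= gp + 20)
        vl_m = (lags >= gv - 20) & (lags <= gv + 20)
        if not pk_m.any() or not vl_m.any():
            continue
        pk = np.argmax(np.where(pk_m, ac, -np.inf))
        vl = np.argmin(np.where(vl_m, ac, np.inf))
        periods[k] = lags[pk]
        p2vs[k] = max(ac[pk] - ac[vl] - 2 * acr.conf_bound, 0.0)

    sleep = (p2vs > p2v_thresh).astype(float)
    kmed = max(int(round(medfilt_s / step_s)) | 1, 1)
    sleep_f = uniform_filter1d(sleep, kmed, mode="nearest") >= binarize
    if not sleep_f.any():
        return SleepInterval(0.0, 0.0), t_bins, periods, p2vs

    runs = np.diff(np.concatenate([[0], sleep_f.astype(int), [0]]))
    run_starts = np.nonzero(runs == 1)[0]
    run_ends = np.nonzero(runs == -1)[0]
    best = np.argmax(run_ends - run_starts)
    interval = SleepInterval(
        float(t_bins[run_starts[best]] - db.window_s),
        float(t_bins[min(run_ends[best] - 1, len(t_bins) - 1)] + bin_s),
    )
    return interval, t_bins, periods, p2vs


def best_oscillation_window(times_s, p2v, width_s: float = 7200.0):
    """Start time of the ``width_s`` window maximizing mean local P2V.

    Ties break to the earliest start; a series shorter than the window
    returns its own start.
    """
    times_s = np.asarray(times_s, float)
    p2v = np.asarray(p2v, float)
    if len(times_s) == 0:
        return 0.0
    step = float(np.median(np.diff(times_s))) if len(times_s) > 1 else width_s
    nwin = int(round(width_s / step))
    if nwin >= len(p2v):
        return float(times_s[0])
    csum = np.concatenate([[0.0], np.cumsum(p2v)])
    means = (csum[nwin:] - csum[:-nwin]) / nwin
    return float(times_s[int(np.argmax(means))])


def segment_cycles(db: DeltaBetaSeries, medfilt_s: float = 20.0,
                   reject_factor: float = 1.5) -> CycleSet:
    """Per-cycle REM/SWS onsets from the Hilbert phase of the delta/beta.

    The series is median filtered, demeaned and Hilbert transformed; the
    peaks of the wrapped instantaneous phase (the wrap points) mark REM
    onsets, and the SWS onset inside each cycle is the minimum of the
    quadrature (imaginary) component of the analytic signal — for a
    near-sinusoidal delta/beta this lands on its rising zero-crossing,
    the REM-to-SWS transition.  Cycles whose duration is more than
    ``reject_factor`` times (or less than 1/``reject_factor`` of) the
    mean are flagged as rejected.
    """
    step = db.step_s
    x = db.values.copy()
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("delta/beta series too short")
    x[~finite] = np.median(x[finite])
    k = max(int(round(medfilt_s / step)) | 1, 1)
    xf = medfilt(x, k)
    xf = xf - xf.mean()
    analytic = signal.hilbert(xf)
    phase = np.angle(analytic)
    wraps, _ = signal.find_peaks(phase, height=0.9 * np.pi, prominence=np.pi)
    if len(wraps) < 4:
        raise ValueError("fewer than 3 cycles detected")
    rem = db.times_s[wraps]
    quad = analytic.imag
    sws = np.array([
        db.times_s[i0 + np.argmin(quad[i0:i1])]
        for i0, i1 in zip(wraps[:-1], wraps[1:])
    ])
    durations = np.diff(rem)
    mean_d = durations.mean()
    kept = (durations <= reject_factor * mean_d) & (durations >= mean_d / reject_factor)
    return CycleSet(rem, sws, durations, kept)


def cycle_phase(t, cycles: CycleSet) -> np.ndarray:
    """Cycle phase in [0, 2pi) of each query time; NaN outside kept cycles.

    Phase 0 at the REM onset opening the cycle, linear in elapsed time.
    """
    t = np.atleast_1d(np.asarray(t, float))
    onsets = cycles.rem_onsets_s
    idx = np.searchsorted(onsets, t, side="right") - 1
    ok = (idx >= 0) & (idx < len(cycles.durations_s))
    idx_c = np.clip(idx, 0, len(cycles.durations_s) - 1)
    ok &= cycles.kept[idx_c]
    with np.errstate(invalid="ignore"):
        ph = 2 * np.pi * (t - onsets[idx_c]) / cycles.durations_s[idx_c]
    return np.where(ok, np.mod(ph, 2 * np.pi), np.nan)


def phase_average(times_s, values, cycles: CycleSet, nbins: int = 36,
                  min_cycles: int = 10):
    """Cycle-phase-resampled average of a signal, min-max normalized to [0, 1].

    Each kept cycle is linearly resampled onto ``nbins`` phase bins and
    the bins are averaged across cycles.  Returns
    ``(bin_center_phases_rad, normalized_curve, raw_curve)``.
    """
    times_s = np.asarray(times_s, float)
    values = np.asarray(values, float)
    if cycles.n_kept < min_cycles:
        raise ValueError(f"need >= {min_cycles} kept cycles")
    centers = (np.arange(nbins) + 0.5) / nbins
    acc = np.zeros(nbins)
    cnt = 0
    for i in np.nonzero(cycles.kept)[0]:
        t0 = cycles.rem_onsets_s[i]
        d = cycles.durations_s[i]
        tq = t0 + centers * d
        if tq[0] < times_s[0] or tq[-1] > times_s[-1]:
            continue
        acc += np.interp(tq, times_s, values)
        cnt += 1
    if cnt == 0:
        raise ValueError("no cycle overlaps the signal support")
    raw = acc / cnt
    rng = np.ptp(raw)
    if rng == 0:
        raise ValueError("constant signal: zero range after averaging")
    return centers * 2 * np.pi, (raw - raw.min()) / rng, raw


def robust_cv(durations) -> float:
    """Robust coefficient of variation: 1.4826 * MAD / median."""
    d = np.asarray(durations, float)
    if len(d) < 5:
        raise ValueError("need at least 5 durations")
    med = np.median(d)
    if med == 0:
        raise ValueError("median duration is zero")
    return float(1.4826 * np.median(np.abs(d - med)) / med)
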