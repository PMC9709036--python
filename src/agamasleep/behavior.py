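"""Behavioral physiology: twitches, breathing, eye movements, and their
phase locking to the sleep cycle.

Micro-movements come from the summed envelope spread of the three
accelerometer axes; breathing from the first principal component of
KLT-tracked ribcage motion in video (or a precomputed displacement
trace); eye movements from windowed Lucas-Kanade optical flow inside a
tracked eye rectangle.  Event phases on the delta/beta cycle clock are
summarized with circular statistics (Rayleigh test), always reported
relative to the delta/beta mean phase, with per-cycle uniform shuffles
as control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates, uniform_filter
from scipy.signal import medfilt

from .cycles import CycleSet, cycle_phase

__all__ = [
    "MovementEvents",
    "BreathingResult",
    "PointTracks",
    "EyeFlowSeries",
    "PhaseStats",
    "movement_detect",
    "movement_profile",
    "breathing_trace",
    "breathing_rate",
    "track_rectangle",
    "eye_flow",
    "eye_events",
    "shuffle_events_in_cycles",
    "event_phase_stats",
    "delta_beta_mean_phase",
    "cooccurrence",
]


@dataclass
class MovementEvents:
    times_s: np.ndarray
    amplitude: np.ndarray    # summed-envelope units
    threshold: float
    noise_sd: float

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class BreathingResult:
    trace: np.ndarray
    rate_hz: float                      # sampling rate of the trace
    times_s: np.ndarray | None = None   # window centers
    rates_hz: np.ndarray | None = None
    amplitudes: np.ndarray | None = None
    rejected: np.ndarray | None = None
    global_peak_lag_s: float = np.nan


@dataclass
class PointTracks:
    positions: np.ndarray       # (frames, max_points, 2) as (x, y), NaN when lost
    fps: float
    redetect_frames: np.ndarray


@dataclass
class EyeFlowSeries:
    times_s: np.ndarray
    magnitude: np.ndarray
    fps: float
    low_confidence: np.ndarray | None = None   # frames with too few points


@dataclass
class PhaseStats:
    n: int
    mean_phase_rad: float        # absolute, on the cycle clock
    relative_phase_rad: float    # relative to the delta/beta mean phase
    resultant_length: float
    rayleigh_p: float


# ---------------------------------------------------------------------------
# micro-movements from accelerometer

def _envelope_spread(x, min_sep=10):
    """Upper minus lower envelope via cubic splines over local extrema.

    Extrema are taken with a minimum separation (default 40 ms at 250 Hz)
    so the envelope follows transient oscillations rather than every
    noise wiggle.
    """
    n = len(x)
    idx = np.arange(n)
    up, _ = signal.find_peaks(x, distance=min_sep)
    lo, _ = signal.find_peaks(-x, distance=min_sep)
    if len(up) < 4 or len(lo) < 4:
        return np.zeros(n)
    up = np.concatenate([[0], up, [n - 1]])
    lo = np.concatenate([[0], lo, [n - 1]])
    upper = CubicSpline(up, x[up])(idx)
    lower = CubicSpline(lo, x[lo])(idx)
    return upper - lower


def movement_detect(accel, in_rate_hz: float, target_rate_hz: float = 250.0,
                    thresh_sd: float = 4.0, kurt_max: float = 3.0,
                    kurt_bin_s: float = 2.0) -> MovementEvents:
    """Micro-movement events from a 3-axis accelerometer.

    Axes are decimated to 250 Hz (Chebyshev anti-aliasing); the per-axis
    upper-lower envelope spread (spline over local extrema) is summed over
    axes.  The noise level is estimated only on 2-s bins whose Pearson
    kurtosis is at most ``kurt_max`` (i.e., not dominated by transients),
    and events are contiguous crossings of noise mean + ``thresh_sd``
    noise SDs, timestamped at their peak.
    """
    accel = np.atleast_2d(np.asarray(accel, float))
    if accel.shape[0] != 3:
        raise ValueError("expect 3 accelerometer axes")
    if in_rate_hz < target_rate_hz:
        raise ValueError("accelerometer rate below 250 Hz")
    q = int(round(in_rate_hz / target_rate_hz))
    if q > 1:
        accel = np.stack([signal.decimate(a, q) for a in accel])
    fs = in_rate_hz / max(q, 1)

    env = np.sum([_envelope_spread(a) for a in accel], axis=0)
    if np.ptp(env) == 0:
        return MovementEvents(np.array([]), np.array([]), 0.0, 0.0)
    # smooth at the sub-twitch time scale (60 ms): suppresses interpolation
    # noise while leaving >=100-ms transients intact
    from scipy.ndimage import uniform_filter1d
    env = uniform_filter1d(env, max(int(0.06 * fs), 1))
    nb = int(kurt_bin_s * fs)
    nbins = len(env) // nb
    if nbins == 0:
        raise ValueError("record shorter than one kurtosis bin")
    bins = env[: nbins * nb].reshape(nbins, nb)
    kurt = stats.kurtosis(bins, axis=1, fisher=False)
    quiet = kurt <= kurt_max
    if not quiet.any():
        raise ValueError("no noise-qualifying bins (all kurtosis above limit)")
    noise = bins[quiet].ravel()
    mu, sd = noise.mean(), noise.std()
    thr = mu + thresh_sd * sd

    above = env > thr
    edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    times, amps = [], []
    for s, e in zip(starts, ends):
        p = s + np.argmax(env[s:e])
        times.append(p / fs)
        amps.append(env[p])
    return MovementEvents(np.array(times), np.array(amps), thr, sd)


def movement_profile(events: MovementEvents, total_s: float,
                     bin_s: float = 3600.0):
    """Integrated supra-threshold amplitude per time bin (default hourly).

    Returns ``(bin_start_s, integrated_amplitude)``.
    """
    edges = np.arange(0, total_s + bin_s, bin_s)
    sums, _ = np.histogram(events.times_s, edges, weights=events.amplitude)
    return edges[:-1], sums


# ---------------------------------------------------------------------------
# KLT point tracking and optical flow (Lucas-Kanade on numpy)

def _lk_track_points(prev, curr, pts, win: int = 7, iters: int = 3):
    """One Lucas-Kanade step: advance ``pts`` (N, 2 as x, y) from ``prev``
    to ``curr``.  Vectorized over points.  Returns (new_pts, valid mask)."""
    prev = np.asarray(prev, float)
    curr = np.asarray(curr, float)
    h, w = prev.shape
    half = win // 2
    dy, dx = np.gradient(prev)
    offs = np.mgrid[-half:half + 1, -half:half + 1].reshape(2, -1)  # (y, x)
    pts = np.asarray(pts, float)
    n = len(pts)
    if n == 0:
        return pts, np.zeros(0, bool)
    valid = ((pts[:, 0] >= half) & (pts[:, 0] < w - half) &
             (pts[:, 1] >= half) & (pts[:, 1] < h - half))
    # window sample coordinates per point: (2, n, win*win)
    cy = pts[:, 1][:, None] + offs[0][None, :]
    cx = pts[:, 0][:, None] + offs[1][None, :]
    coords = np.stack([np.clip(cy, 0, h - 1), np.clip(cx, 0, w - 1)])
    flat = coords.reshape(2, -1)
    ix = map_coordinates(dx, flat, order=1).reshape(n, -1)
    iy = map_coordinates(dy, flat, order=1).reshape(n, -1)
    i0 = map_coordinates(prev, flat, order=1).reshape(n, -1)
    a11 = np.sum(ix * ix, axis=1)
    a12 = np.sum(ix * iy, axis=1)
    a22 = np.sum(iy * iy, axis=1)
    det = a11 * a22 - a12 ** 2
    valid &= det > 1e-6
    det = np.where(valid, det, 1.0)
    u = np.zeros((n, 2))  # (dx, dy)
    for _ in range(iters):
        c2y = np.clip(coords[0] + u[:, 1][:, None], 0, h - 1)
        c2x = np.clip(coords[1] + u[:, 0][:, None], 0, w - 1)
        i1 = map_coordinates(curr, np.stack([c2y, c2x]).reshape(2, -1),
                             order=1).reshape(n, -1)
        it = i1 - i0
        b1 = -np.sum(ix * it, axis=1)
        b2 = -np.sum(iy * it, axis=1)
        u[:, 0] += (a22 * b1 - a12 * b2) / det
        u[:, 1] += (-a12 * b1 + a11 * b2) / det
    new = pts + u
    valid &= ((new[:, 0] >= 0) & (new[:, 0] < w) &
              (new[:, 1] >= 0) & (new[:, 1] < h))
    return new, valid


def _detect_corners(frame, rect, max_points: int = 80, min_distance: int = 1):
    """Minimum-eigenvalue (Shi-Tomasi) corner points inside ``rect``
    (x, y, w, h)."""
    from skimage.feature import corner_peaks, corner_shi_tomasi
    x, y, w, h = rect
    sub = np.asarray(frame[y:y + h, x:x + w], float)
    sub = sub - sub.mean()   # avoid zero-padding border responses
    resp = corner_shi_tomasi(sub)
    if resp.max() <= 1e-9:
        return np.empty((0, 2))
    peaks = corner_peaks(resp, min_distance=min_distance,
                         threshold_rel=0.001, num_peaks=max_points)
    if len(peaks) == 0:
        return np.empty((0, 2))
    return np.column_stack([peaks[:, 1] + x, peaks[:, 0] + y]).astype(float)


def track_rectangle(frames, rect, fps: float, redetect_every_s: float = 100.0,
                    min_points: int = 40, drop_frac: float = 0.10,
                    max_points: int = 60) -> PointTracks:
    """KLT tracking of corner points seeded inside a rectangle.

    Points are re-detected on a ``redetect_every_s`` schedule, or whenever
    fewer than ``min_points`` survive or more than ``drop_frac`` of them
    are lost in one step; re-detection frames are reported so they can be
    excluded from analysis.
    """
    frames = np.asarray(frames)
    nf, h, w = frames.shape
    x, y, rw, rh = rect
    if x < 0 or y < 0 or x + rw > w or y + rh > h:
        raise ValueError("rect outside frame")
    pts = _detect_corners(frames[0], rect, max_points)
    if len(pts) == 0:
        raise ValueError("zero corners found in the seed rectangle")
    positions = np.full((nf, max_points, 2), np.nan)
    positions[0, : len(pts)] = pts
    redetect = [0]
    every = max(int(round(redetect_every_s * fps)), 1)
    n_prev = len(pts)
    for i in range(1, nf):
        pts, valid = _lk_track_points(frames[i - 1], frames[i], pts)
        pts = pts[valid]
        need = (i % every == 0 or len(pts) < min_points
                or len(pts) < (1 - drop_frac) * n_prev)
        if need:
            pts = _detect_corners(frames[i], rect, max_points)
            redetect.append(i)
            if len(pts) == 0:
                raise ValueError(f"zero corners found at frame {i}")
        positions[i, : len(pts)] = pts[:max_points]
        n_prev = len(pts)
    return PointTracks(positions, fps, np.array(redetect))


# ---------------------------------------------------------------------------
# breathing

def breathing_trace(tracks: PointTracks) -> BreathingResult:
    """Breathing displacement: PC1 of the tracked mean (x, y) motion.

    The per-frame mean point position is median filtered (2-s window);
    frames at point re-detection are excluded (interpolated across).  The
    sign convention makes the dominant-axis loading positive.
    """
    from sklearn.decomposition import PCA
    pos = np.nanmean(tracks.positions, axis=1)   # (frames, 2)
    valid = np.isfinite(pos).all(axis=1)
    valid[tracks.redetect_frames] = False
    n = len(pos)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid frames")
    idx = np.arange(n)
    for c in range(2):
        pos[:, c] = np.interp(idx, idx[valid], pos[valid, c])
    k = max(int(round(2.0 * tracks.fps)) | 1, 1)
    pos = np.column_stack([medfilt(pos[:, c], k) for c in range(2)])
    pos -= pos.mean(axis=0)
    if np.allclose(pos, 0):
        raise ValueError("static points: zero variance")
    pca = PCA(n_components=2).fit(pos)
    comp = pca.components_[0]
    if comp[np.argmax(np.abs(comp))] < 0:
        comp = -comp
    trace = pos @ comp
    res = BreathingResult(trace, tracks.fps)
    res.pc1_explained = float(pca.explained_variance_ratio_[0])
    return res


def breathing_rate(trace, fs: float, win_s: float = 24.0, overlap: float = 0.5,
                   peak_lo_s: float = 2.5, peak_hi_s: float = 5.0,
                   amp_medfilt_s: float = 0.0) -> BreathingResult:
    """Windowed breathing rate and amplitude from autocorrelation peaks.

    The global peak lag GP comes from the whole-trace autocorrelation;
    each 24-s window (50% overlap) contributes ``1 / local peak lag``
    where the local peak is the first autocorrelation peak inside
    ``[GP - peak_lo_s, GP + peak_hi_s]``.  Windows whose first valley lag
    exceeds their peak lag (noise) are rejected.  Amplitude is the
    per-window peak-to-trough of the median-filtered trace; a trace from
    ``breathing_trace`` is already 2-s median filtered, so the default
    applies no further filtering (set ``amp_medfilt_s=2`` for raw input).
    """
    x = np.asarray(trace, float)
    nwin = int(win_s * fs)
    if len(x) < nwin:
        raise ValueError("trace shorter than one window")
    hop = max(int(nwin * (1 - overlap)), 1)

    def _acorr(seg):
        seg = seg - seg.mean()
        ac = signal.correlate(seg, seg, mode="full")[len(seg) - 1:]
        return ac / ac[0] if ac[0] > 0 else ac

    ac = _acorr(x)
    peaks, _ = signal.find_peaks(ac, prominence=0.05)
    if len(peaks) == 0:
        raise ValueError("no global autocorrelation peak: no breathing rhythm")
    gp = peaks[0] / fs

    if amp_medfilt_s > 0:
        k2 = max(int(round(amp_medfilt_s * fs)) | 1, 1)
        xmed = medfilt(x, k2)
    else:
        xmed = x

    times, rates, amps, rejected = [], [], [], []
    lo = max(int((gp - peak_lo_s) * fs), 1)
    hi = int((gp + peak_hi_s) * fs)
    # only prominent local peaks qualify (above the white-noise wiggle
    # scale of a window's autocorrelation); the valley is the deepest
    # point before the search limit
    min_prom = 2.0 / np.sqrt(nwin)
    for s0 in range(0, len(x) - nwin + 1, hop):
        seg = x[s0:s0 + nwin]
        times.append((s0 + nwin / 2) / fs)
        amps.append(np.ptp(xmed[s0:s0 + nwin]))
        a = _acorr(seg)
        pk, _ = signal.find_peaks(a[: hi + 1], prominence=min_prom)
        pk = pk[(pk >= lo) & (pk <= hi)]
        peak_lag = pk[0] if len(pk) else np.nan
        valley_lag = 1 + np.argmin(a[1: hi + 1])
        bad = (not np.isfinite(peak_lag)) or valley_lag > peak_lag
        rejected.append(bad)
        rates.append(np.nan if bad else fs / peak_lag)
    return BreathingResult(
        x, fs, np.array(times), np.array(rates), np.array(amps),
        np.array(rejected), gp)


# ---------------------------------------------------------------------------
# eye movements

def _dense_lk_flow(prev, curr, win: int = 5):
    """Dense Lucas-Kanade flow between two small grayscale patches.

    Returns (u, v, min_eigenvalue) arrays; flow is solved per pixel from
    window-summed gradient products.
    """
    prev = np.asarray(prev, float)
    curr = np.asarray(curr, float)
    iy, ix = np.gradient(prev)
    it = curr - prev
    sxx = uniform_filter(ix * ix, win)
    sxy = uniform_filter(ix * iy, win)
    syy = uniform_filter(iy * iy, win)
    sxt = uniform_filter(ix * it, win)
    syt = uniform_filter(iy * it, win)
    det = sxx * syy - sxy ** 2
    tr = sxx + syy
    mineig = tr / 2 - np.sqrt(np.maximum(tr ** 2 / 4 - det, 0))
    safe = np.abs(det) > 1e-9
    u = np.where(safe, (-syy * sxt + sxy * syt) / np.where(safe, det, 1), 0)
    v = np.where(safe, (sxy * sxt - sxx * syt) / np.where(safe, det, 1), 0)
    return u, v, mineig


def eye_flow(frames, eye_rect, fps: float = 5.0, rect_update_hz: float = 0.6,
             dev_frac: float = 0.25, min_points: int = 3,
             edge_px: int = 5, eig_thresh: float = 1.0) -> EyeFlowSeries:
    """Mean Lucas-Kanade flow magnitude inside a tracked eye rectangle.

    Flow is computed between consecutive frames (expected at 5 Hz) over
    the rectangle interior (``edge_px`` border excluded).  The rectangle
    follows the accumulated flow displacement, checked at
    ``rect_update_hz``: it moves only when the candidate deviates by more
    than ``dev_frac`` of the width or height in that dimension.  Frames
    with fewer than ``min_points`` well-conditioned pixels are flagged.
    """
    frames = np.asarray(frames)
    nf, fh, fw = frames.shape
    x, y, w, h = (int(v) for v in eye_rect)
    mags = np.zeros(nf)
    lowconf = np.zeros(nf, bool)
    acc = np.zeros(2)
    check_every = max(int(round(fps / rect_update_hz)), 1)
    for i in range(1, nf):
        p = frames[i - 1][y:y + h, x:x + w]
        c = frames[i][y:y + h, x:x + w]
        u, v, eig = _dense_lk_flow(p, c)
        inner = (slice(edge_px, h - edge_px), slice(edge_px, w - edge_px))
        good = eig[inner] > eig_thresh
        if good.sum() < min_points:
            lowconf[i] = True
            continue
        mags[i] = np.mean(np.hypot(u[inner], v[inner]))
        acc += (np.median(u[inner][good]), np.median(v[inner][good]))
        if i % check_every == 0:
            if abs(acc[0]) > dev_frac * w:
                x = int(np.clip(x + round(acc[0]), 0, fw - w))
                acc[0] = 0
            if abs(acc[1]) > dev_frac * h:
                y = int(np.clip(y + round(acc[1]), 0, fh - h))
                acc[1] = 0
    return EyeFlowSeries(np.arange(nf) / fps, mags, fps, lowconf)


def eye_events(flow: EyeFlowSeries, mad_mult: float = 6.0,
               window_s: float = 180.0, cycles: CycleSet | None = None,
               rng=None):
    """Significant eye movements by a floating median + 6-MAD threshold.

    The threshold floats over a 3-min window.  If ``cycles`` is given, a
    shuffled control with the same per-cycle event counts but uniform
    times over each cycle is returned as well.

    Returns ``(event_times_s, surrogate_times_s or None)``.
    """
    nwin = int(window_s * flow.fps)
    if len(flow.magnitude) < nwin:
        raise ValueError("flow series shorter than the floating window")
    s = pd.Series(flow.magnitude)
    med = s.rolling(nwin, center=True, min_periods=1).median().to_numpy()
    mad = (s - med).abs().rolling(nwin, center=True, min_periods=1)\
        .median().to_numpy()
    above = flow.magnitude > med + mad_mult * mad
    edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    times = np.array([
        flow.times_s[s0 + np.argmax(flow.magnitude[s0:e0])]
        for s0, e0 in zip(starts, ends)
    ])
    surrogate = None
    if cycles is not None:
        surrogate = shuffle_events_in_cycles(times, cycles, rng)
    return times, surrogate


def shuffle_events_in_cycles(times_s, cycles: CycleSet, rng=None) -> np.ndarray:
    """Per-cycle uniform surrogate preserving each cycle's event count."""
    rng = np.random.default_rng(rng)
    out = []
    for i in np.nonzero(cycles.kept)[0]:
        r0, r1 = cycles.rem_onsets_s[i], cycles.rem_onsets_s[i + 1]
        k = np.sum((np.asarray(times_s) >= r0) & (np.asarray(times_s) < r1))
        out.append(rng.uniform(r0, r1, k))
    return np.sort(np.concatenate(out)) if out else np.array([])


# ---------------------------------------------------------------------------
# circular phase statistics

def delta_beta_mean_phase(db_times_s, db_values, cycles: CycleSet) -> float:
    """Delta/beta-weighted circular mean phase on the cycle clock."""
    ph = cycle_phase(db_times_s, cycles)
    w = np.asarray(db_values, float)
    ok = np.isfinite(ph) & np.isfinite(w)
    z = np.sum(w[ok] * np.exp(1j * ph[ok]))
    return float(np.mod(np.angle(z), 2 * np.pi))


def event_phase_stats(event_times_s, cycles: CycleSet, db_times_s=None,
                      db_values=None, min_events: int = 10) -> PhaseStats:
    """Circular mean phase and Rayleigh uniformity test of event phases.

    Phases come from the cycle clock; when a delta/beta series is given,
    the mean phase is also expressed relative to the delta/beta circular
    mean phase, the field-standard reference frame for state locking.
    """
    from pingouin import circ_rayleigh
    ph = cycle_phase(np.asarray(event_times_s, float), cycles)
    ph = ph[np.isfinite(ph)]
    if len(ph) < min_events:
        raise ValueError(f"need >= {min_events} events inside kept cycles")
    z = np.mean(np.exp(1j * ph))
    mean_phase = float(np.mod(np.angle(z), 2 * np.pi))
    _, pval = circ_rayleigh(ph)
    rel = np.nan
    if db_times_s is not None:
        ref = delta_beta_mean_phase(db_times_s, db_values, cycles)
        rel = float(np.mod(mean_phase - ref, 2 * np.pi))
    return PhaseStats(len(ph), mean_phase, rel, float(np.abs(z)), float(pval))


# ---------------------------------------------------------------------------
# co-occurrence of movement sources

def cooccurrence(times_a, times_b, tol_s: float = 1.0, amps_a=None,
                 amps_b=None, trace_a=None, trace_b=None,
                 trace_fs: float = 1.0, max_lag_s: float = 10.0):
    """Co-occurrence fractions, amplitude correlation, and trace cross-
    correlation between two event sources.

    Returns a dict with the fraction of A events within ``tol_s`` of a B
    event (and vice versa), the Pearson r (with p) of amplitudes on
    co-occurring pairs, and the maximum absolute normalized
    cross-correlation of the two traces over +/-``max_lag_s``.
    """
    a = np.sort(np.asarray(times_a, float))
    b = np.sort(np.asarray(times_b, float))
    out = {"n_a": len(a), "n_b": len(b), "empty": len(a) == 0 or len(b) == 0}

    def frac_within(u, v):
        if len(u) == 0 or len(v) == 0:
            return 0.0
        i = np.searchsorted(v, u)
        left = np.abs(u - v[np.clip(i - 1, 0, len(v) - 1)])
        right = np.abs(v[np.clip(i, 0, len(v) - 1)] - u)
        return float(np.mean(np.minimum(left, right) <= tol_s))

    out["frac_a_near_b"] = frac_within(a, b)
    out["frac_b_near_a"] = frac_within(b, a)

    out["amp_r"] = out["amp_p"] = np.nan
    if amps_a is not None and amps_b is not None and len(a) and len(b):
        amps_a = np.asarray(amps_a, float)
        amps_b = np.asarray(amps_b, float)
        pa, pb = [], []
        j = np.searchsorted(b, a)
        for k, t in enumerate(a):
            cand = [c for c in (j[k] - 1, j[k]) if 0 <= c < len(b)]
            if not cand:
                continue
            c = min(cand, key=lambda c: abs(b[c] - t))
            if abs(b[c] - t) <= tol_s:
                pa.append(amps_a[k])
                pb.append(amps_b[c])
        if len(pa) > 2 and np.ptp(pa) > 0 and np.ptp(pb) > 0:
            r, p = stats.pearsonr(pa, pb)
            out["amp_r"], out["amp_p"] = float(r), float(p)
        out["n_pairs"] = len(pa)

    out["max_xcorr"] = np.nan
    if trace_a is not None and trace_b is not None:
        ta = np.asarray(trace_a, float) - np.mean(trace_a)
        tb = np.asarray(trace_b, float) - np.mean(trace_b)
        n = min(len(ta), len(tb))
        ta, tb = ta[:n], tb[:n]
        if ta.std() > 0 and tb.std() > 0:
            nlag = int(max_lag_s * trace_fs)
            full = signal.correlate(ta, tb, mode="full") / (n * ta.std() * tb.std())
            mid = n - 1
            out["max_xcorr"] = float(
                np.abs(full[mid - nlag: mid + nlag + 1]).max())
    return out
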