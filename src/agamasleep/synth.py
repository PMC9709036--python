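"""Synthetic two-state sleep recordings with known ground truth.

Generates multichannel surrogates of a lizard sleep night: an LFP that
alternates between a slow-wave state (SWS-like, power below 4 Hz, with
sharp-wave transients) and a REM-like state (power concentrated in the
10-40 Hz band), together with population spikes, 3-axis accelerometer
traces with twitch transients, a breathing displacement trace, eye and
twitch events phase-locked to the sleep cycle, an ambient-temperature
logger series, and (optionally) grayscale video frames.

The cycle period scales with ambient temperature following the Q10 rule

    P(T) = period_at_t0_s / q10 ** ((T - t0_c) / 10)

so nights generated across a temperature range embody the Arrhenius
scaling the downstream fits are supposed to recover.  Signals are
statistical surrogates, not biophysical simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import warnings

import numpy as np
from scipy import signal
from scipy.ndimage import map_coordinates

__all__ = [
    "GenConfig",
    "GroundTruth",
    "Recording",
    "cycle_period_at",
    "synth_state_sequence",
    "synth_lfp",
    "synth_phase_locked_events",
    "synth_accel_breath",
    "synth_video",
    "generate_recording",
    "shw_waveform",
]

SWS = "SWS"
REM = "REM"


@dataclass
class GenConfig:
    """Parameters of one synthetic night.

    Rates are per second, amplitudes in microvolts, durations in seconds.
    ``t0_c``/``q10``/``period_at_t0_s`` set the Arrhenius cycle-period
    scaling; the default reference period gives a 92.8-s cycle at 27 degC.
    """

    duration_s: float = 3600.0
    lfp_rate_hz: float = 2000.0
    temperature_c: float = 27.0
    t0_c: float = 17.0
    q10: float = 2.3
    period_at_t0_s: float = 213.44  # 92.8 s at 27 degC
    sws_fraction: float = 0.55
    period_cv: float = 0.1          # lognormal cycle-duration jitter
    wake_s: float = 0.0             # quiescent margin at each record edge

    # LFP composition
    sws_rms_uv: float = 120.0
    rem_rms_uv: float = 90.0
    sws_beta_leak: float = 0.3    # residual beta-kernel amplitude in SWS
    rem_delta_leak: float = 0.08  # residual delta-kernel amplitude in REM
    wake_rms_uv: float = 25.0
    noise_sd_uv: float = 20.0

    # sharp waves and ripples
    shw_rate_sws_hz: float = 0.4
    shw_rate_rem_hz: float = 0.02
    shw_width_ms: float = 120.0
    shw_amp_uv: float = 450.0
    ripple_freq_hz: float = 100.0
    ripple_amp_uv: float = 35.0

    # spiking
    spike_rate_rem_hz: float = 20.0
    spike_rate_sws_hz: float = 2.0
    spike_burst_prob_sws: float = 0.8
    spike_burst_size: float = 5.0   # Poisson mean spikes per ShW burst

    # phase-locked behavioral events (cycle clock: 0 = SWS onset)
    twitch_rate_per_cycle: float = 1.5
    twitch_phase_rad: float = 4.9   # mid-REM
    twitch_kappa: float = 6.0
    eye_event_rate_per_cycle: float = 2.0
    eye_phase_rad: float = 4.7
    eye_kappa: float = 6.0

    # breathing and accelerometer
    breath_rate_sws_hz: float = 0.12
    breath_rate_rem_hz: float = 0.25
    breath_amp_ratio: float = 1.5   # REM amplitude / SWS amplitude
    breath_amp_px: float = 3.0
    accel_rate_hz: float = 500.0
    accel_noise_sd: float = 1.0
    twitch_amp_sd: float = 15.0     # transient peak in units of baseline SD

    # temperature side effects (power grows, ShW narrow with warming)
    temp_power_coeff: float = 0.05  # fractional LFP power gain per degC
    temp_width_coeff: float = 0.03  # ShW width shrink factor per degC

    # video
    video_fps: float = 0.0          # 0 disables frame synthesis
    frame_shape: tuple = (96, 96)
    video_noise_sd: float = 1.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if not 0 < self.sws_fraction < 1:
            raise ValueError("sws_fraction must lie in (0, 1)")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")
        for name in (
            "shw_rate_sws_hz", "shw_rate_rem_hz", "spike_rate_rem_hz",
            "spike_rate_sws_hz", "twitch_rate_per_cycle",
            "eye_event_rate_per_cycle", "breath_rate_sws_hz",
            "breath_rate_rem_hz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.twitch_kappa < 0 or self.eye_kappa < 0:
            raise ValueError("von Mises concentration must be >= 0")

    @property
    def cycle_period_s(self) -> float:
        return cycle_period_at(
            self.temperature_c, self.period_at_t0_s, self.q10, self.t0_c
        )

    def to_dict(self) -> dict:
        return asdict(self)


def cycle_period_at(temperature_c, period_at_t0_s, q10, t0_c):
    """Q10-scaled cycle period: P(T) = P(T0) / q10**((T - T0)/10)."""
    return period_at_t0_s / q10 ** ((temperature_c - t0_c) / 10.0)


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator knows about one night."""

    state_intervals: list        # (start_s, end_s, label) half-open, tiled
    cycle_starts_s: np.ndarray   # SWS onsets, one per full cycle
    cycle_periods_s: np.ndarray
    shw_times_s: np.ndarray
    twitch_times_s: np.ndarray
    eye_times_s: np.ndarray
    spike_times_s: np.ndarray
    breath_rate_hz: np.ndarray   # instantaneous rate, 1 Hz sampling
    cycle_period_s: float        # configured mean period

    def rem_onsets_s(self) -> np.ndarray:
        return np.array([s for s, _, lab in self.state_intervals if lab == REM])

    def state_at(self, times_s) -> np.ndarray:
        """Label ('SWS'/'REM'/'' outside sleep) for each query time."""
        times_s = np.atleast_1d(np.asarray(times_s, float))
        out = np.full(times_s.shape, "", dtype=object)
        for s, e, lab in self.state_intervals:
            out[(times_s >= s) & (times_s < e)] = lab
        return out

    def cycle_phase(self, times_s) -> np.ndarray:
        """Ground-truth cycle phase in [0, 2pi); NaN outside full cycles."""
        times_s = np.asarray(times_s, float)
        starts = self.cycle_starts_s
        ends = starts + self.cycle_periods_s
        idx = np.searchsorted(starts, times_s, side="right") - 1
        idx = np.clip(idx, 0, len(starts) - 1)
        phase = 2 * np.pi * (times_s - starts[idx]) / self.cycle_periods_s[idx]
        phase = np.where((times_s >= starts[idx]) & (times_s < ends[idx]),
                         phase, np.nan)
        return phase


@dataclass
class Recording:
    """Time-aligned multichannel container for one night.

    All times are seconds from recording start; sample index 0 is t = 0.
    """

    lfp: np.ndarray              # (channels, samples), microvolts
    lfp_rate_hz: float
    accel: np.ndarray | None = None         # (3, samples)
    accel_rate_hz: float = 0.0
    temperature_time_s: np.ndarray | None = None
    temperature_c: np.ndarray | None = None
    spike_times_s: np.ndarray | None = None
    breath_displacement: np.ndarray | None = None  # pixels, at breath_rate_hz
    breath_displacement_rate_hz: float = 0.0
    video: np.ndarray | None = None         # (frames, h, w) uint8
    video_fps: float = 0.0
    start_time: str = ""
    seed: int | None = None

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.lfp_rate_hz


# ---------------------------------------------------------------------------
# state sequence

def synth_state_sequence(cfg: GenConfig, rng: np.random.Generator | None = None):
    """Alternating SWS/REM intervals tiling the sleep span of the record.

    Each cycle is an SWS segment of ``sws_fraction * P`` followed by a REM
    segment; cycle durations are lognormally jittered with CV
    ``period_cv`` around the Q10-scaled period.  Returns
    ``(intervals, cycle_starts, cycle_periods)``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    period = cfg.cycle_period_s
    sleep_start = cfg.wake_s
    sleep_end = cfg.duration_s - cfg.wake_s
    span = sleep_end - sleep_start
    if span < period:
        warnings.warn("record shorter than one sleep cycle; no states generated")
        return [], np.array([]), np.array([])

    if cfg.period_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.period_cv ** 2))
        mu = np.log(period) - sigma ** 2 / 2.0
        n_guess = int(np.ceil(span / period * 2)) + 5
        periods = rng.lognormal(mu, sigma, n_guess)
    else:
        periods = np.full(int(np.ceil(span / period)) + 1, period)

    starts, kept = [], []
    t = sleep_start
    for p in periods:
        if t + p > sleep_end + 1e-9:
            break
        starts.append(t)
        kept.append(p)
        t += p
    starts = np.asarray(starts)
    kept = np.asarray(kept)

    intervals = []
    for s, p in zip(starts, kept):
        intervals.append((s, s + cfg.sws_fraction * p, SWS))
        intervals.append((s + cfg.sws_fraction * p, s + p, REM))
    return intervals, starts, kept


# ---------------------------------------------------------------------------
# LFP

def shw_waveform(width_ms: float, rate_hz: float) -> np.ndarray:
    """Sharp-wave kernel: biphasic difference of Gaussians, negative peak -1.

    ``width_ms`` is approximately the full width at half maximum of the
    main (negative) deflection.
    """
    s1 = width_ms / 1000.0 / 2.355
    s2 = 2.0 * s1
    t = np.arange(-4 * s2, 4 * s2, 1.0 / rate_hz)
    w = np.exp(-t ** 2 / (2 * s1 ** 2)) - 0.55 * np.exp(-t ** 2 / (2 * s2 ** 2))
    w -= w.mean()
    w /= np.abs(w).max()
    return -w


def _band_noise(n, fs, band, rng, order=4):
    """Unit-variance Gaussian noise shaped into a frequency band."""
    x = rng.standard_normal(n)
    if band[0] <= 0:
        sos = signal.butter(order, band[1], "lowpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, band, "bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _poisson_times(rng, rate_hz, start, end, min_sep=0.0):
    if rate_hz <= 0 or end <= start:
        return np.array([])
    n = rng.poisson(rate_hz * (end - start))
    t = np.sort(rng.uniform(start, end, n))
    if min_sep > 0 and len(t) > 1:
        keep = np.concatenate([[True], np.diff(t) >= min_sep])
        t = t[keep]
    return t


def synth_lfp(cfg: GenConfig, intervals, rng: np.random.Generator | None = None):
    """One LFP channel realizing the given state sequence.

    SWS segments carry low-pass (<4 Hz) noise plus injected sharp-wave
    transients (each optionally carrying a ripple-band burst at its
    trough); REM segments carry 10-40 Hz band noise; wake margins carry
    weak white noise.  Broadband noise of ``noise_sd_uv`` is added
    throughout.  Power scales with temperature by
    ``1 + temp_power_coeff * (T - t0)`` and ShW width shrinks as
    ``1 / (1 + temp_width_coeff * (T - t0))``.

    Returns ``(lfp, shw_times_s)``.
    """
    fs = cfg.lfp_rate_hz
    if fs < 500:
        raise ValueError("lfp_rate_hz must be >= 500 to carry the ripple band")
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = int(round(cfg.duration_s * fs))
    if n == 0:
        return np.zeros(0), np.array([])

    gain = np.sqrt(max(1.0 + cfg.temp_power_coeff *
                       (cfg.temperature_c - cfg.t0_c), 0.05))
    width_ms = cfg.shw_width_ms / (
        1.0 + cfg.temp_width_coeff * (cfg.temperature_c - cfg.t0_c))

    # REM kernel: gentle low edge (order 2 from 6 Hz) so that the two state
    # spectra cross a few Hz above the delta band, as real spectra do
    delta_k = _band_noise(n, fs, (0.0, 4.0), rng) * cfg.sws_rms_uv * gain
    beta_k = _band_noise(n, fs, (6.0, 40.0), rng, order=2) * cfg.rem_rms_uv * gain
    # each state keeps a residual of the opposite kernel, as real spectra
    # do; this bounds the delta/beta ratio's dynamic range
    sws_noise = delta_k + cfg.sws_beta_leak * beta_k
    rem_noise = beta_k + cfg.rem_delta_leak * delta_k

    t = np.arange(n) / fs
    lfp = rng.standard_normal(n) * cfg.wake_rms_uv  # wake / gaps baseline
    shw_times = []
    for s, e, lab in intervals:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        src = sws_noise if lab == SWS else rem_noise
        lfp[i0:i1] = src[i0:i1]
        rate = cfg.shw_rate_sws_hz if lab == SWS else cfg.shw_rate_rem_hz
        shw_times.append(_poisson_times(rng, rate, s, e, min_sep=0.3))
    shw_times = np.sort(np.concatenate(shw_times)) if shw_times else np.array([])

    if len(shw_times):
        kern = shw_waveform(width_ms, fs) * cfg.shw_amp_uv * gain
        half = len(kern) // 2
        ripple = None
        if cfg.ripple_amp_uv > 0 and cfg.ripple_freq_hz < fs / 2:
            tr = (np.arange(len(kern)) - half) / fs
            env = np.exp(-tr ** 2 / (2 * (width_ms / 4000.0) ** 2))
            ripple = (cfg.ripple_amp_uv * gain * env *
                      np.sin(2 * np.pi * cfg.ripple_freq_hz * tr))
        for ts in shw_times:
            i = int(round(ts * fs))
            lo, hi = i - half, i - half + len(kern)
            if lo < 0 or hi > n:
                continue
            lfp[lo:hi] += kern
            if ripple is not None:
                lfp[lo:hi] += ripple

    if cfg.noise_sd_uv > 0:
        lfp += rng.standard_normal(n) * cfg.noise_sd_uv
    return lfp, shw_times


# ---------------------------------------------------------------------------
# phase-locked events, spikes

def synth_phase_locked_events(cfg: GenConfig, cycle_starts, cycle_periods,
                              rate_per_cycle, mu_rad, kappa,
                              rng: np.random.Generator | None = None):
    """Event times with von Mises phase locking to the cycle clock.

    The cycle clock runs 0 -> 2pi from each SWS onset to the next; per-cycle
    counts are Poisson(``rate_per_cycle``); ``kappa = 0`` gives circularly
    uniform phases.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    times = []
    for s, p in zip(cycle_starts, cycle_periods):
        k = rng.poisson(rate_per_cycle)
        if k == 0:
            continue
        if kappa == 0:
            ph = rng.uniform(0, 2 * np.pi, k)
        else:
            ph = np.mod(rng.vonmises(mu_rad, kappa, k), 2 * np.pi)
        times.append(s + ph / (2 * np.pi) * p)
    return np.sort(np.concatenate(times)) if times else np.array([])


def _synth_spikes(cfg: GenConfig, intervals, shw_times, rng):
    """Tonic REM spiking vs sparse SWS spiking with bursts riding ShW."""
    trains = []
    for s, e, lab in intervals:
        rate = cfg.spike_rate_rem_hz if lab == REM else cfg.spike_rate_sws_hz
        trains.append(_poisson_times(rng, rate, s, e))
    for ts in shw_times:
        if rng.uniform() < cfg.spike_burst_prob_sws:
            k = rng.poisson(cfg.spike_burst_size)
            trains.append(ts + rng.normal(0, 0.015, k))
    if not trains:
        return np.array([])
    t = np.sort(np.concatenate(trains))
    return t[(t >= 0) & (t < cfg.duration_s)]


# ---------------------------------------------------------------------------
# accelerometer and breathing

def synth_accel_breath(cfg: GenConfig, intervals, twitch_times,
                       rng: np.random.Generator | None = None):
    """3-axis accelerometer with twitch transients, plus a breathing trace.

    Accelerometer axes are baseline Gaussian noise; each twitch adds a
    damped-oscillation transient with peak ``twitch_amp_sd`` baseline SDs,
    split across axes.  Breathing is a phase-continuous sinusoid whose
    instantaneous rate is ``breath_rate_sws_hz``/``breath_rate_rem_hz`` by
    state and whose amplitude is larger in REM by ``breath_amp_ratio``.

    Returns ``(accel (3, n), breath displacement at accel rate, inst rate at 1 Hz)``.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    fs = cfg.accel_rate_hz
    n = int(round(cfg.duration_s * fs))
    accel = rng.standard_normal((3, n)) * cfg.accel_noise_sd

    kern_t = np.arange(0, 0.25, 1 / fs)
    kern = np.exp(-kern_t / 0.05) * np.sin(2 * np.pi * 12 * kern_t)
    kern /= np.abs(kern).max()
    for ts in np.asarray(twitch_times):
        i = int(round(ts * fs))
        if i < 0 or i + len(kern) > n:
            continue
        w = rng.dirichlet(np.ones(3))
        amp = cfg.twitch_amp_sd * cfg.accel_noise_sd
        for ax in range(3):
            accel[ax, i:i + len(kern)] += amp * w[ax] * kern

    t = np.arange(n) / fs
    rate = np.full(n, cfg.breath_rate_sws_hz)
    amp = np.full(n, 1.0)
    for s, e, lab in intervals:
        if lab == REM:
            m = (t >= s) & (t < e)
            rate[m] = cfg.breath_rate_rem_hz
            amp[m] = cfg.breath_amp_ratio
    phase = 2 * np.pi * np.cumsum(rate) / fs
    breath = cfg.breath_amp_px * amp * np.sin(phase)

    t1 = np.arange(int(cfg.duration_s))
    inst_rate = rate[np.minimum((t1 * fs).astype(int), max(n - 1, 0))] if n else np.array([])
    return accel, breath, inst_rate


# ---------------------------------------------------------------------------
# video

def _texture(shape, rng, contrast=60.0, smooth=0.8):
    """Speckle texture with enough corner structure for feature tracking."""
    from scipy.ndimage import gaussian_filter
    tex = gaussian_filter(rng.standard_normal(shape), smooth)
    tex -= tex.mean()
    tex *= contrast / max(tex.std(), 1e-9)
    return tex


def synth_video(cfg: GenConfig, breath_trace, eye_times,
                rng: np.random.Generator | None = None,
                rib_rect=None, eye_rect=None):
    """Grayscale frame stack: a textured 'ribcage' patch translating with
    the breathing trace and a textured 'eye' patch shifting briefly at eye
    events, over a static noisy background.

    ``breath_trace`` must be sampled at ``cfg.video_fps``.  Patch
    rectangles (x, y, w, h) default to fixed fractions of the frame and
    must lie inside it.  Returns ``(frames uint8 (n, h, w), rib_rect,
    eye_rect)``.
    """
    fps = cfg.video_fps
    if fps < 5:
        raise ValueError("video frame rate must be >= 5 Hz")
    rng = np.random.default_rng(cfg.seed + 4) if rng is None else rng
    h, w = cfg.frame_shape
    nf = int(round(cfg.duration_s * fps))
    if rib_rect is None:
        rib_rect = (int(w * 0.1), int(h * 0.45), int(w * 0.42), int(h * 0.42))
    if eye_rect is None:
        eye_rect = (int(w * 0.62), int(h * 0.08), int(w * 0.26), int(h * 0.26))
    for x, y, rw, rh in (rib_rect, eye_rect):
        if x < 0 or y < 0 or x + rw > w or y + rh > h:
            raise ValueError("patch outside frame bounds")

    background = 90.0 + _texture((h, w), rng, contrast=10.0, smooth=3.0)
    rib_tex = _texture((rib_rect[3], rib_rect[2]), rng, contrast=45.0)
    eye_tex = _texture((eye_rect[3], eye_rect[2]), rng, contrast=45.0)

    breath_trace = np.asarray(breath_trace, float)
    # saccade-like eye shifts: the patch jumps 3 px at each event and stays,
    # alternating direction, so each event is a single flow transient
    eye_offset = np.zeros(nf)
    direction = 1.0
    for ts in np.asarray(eye_times):
        i = int(round(ts * fps))
        if 0 <= i < nf:
            eye_offset[i:] = eye_offset[i] + 3.0 * direction
            direction = -direction

    yy_r, xx_r = np.mgrid[0:rib_rect[3], 0:rib_rect[2]].astype(float)
    yy_e, xx_e = np.mgrid[0:eye_rect[3], 0:eye_rect[2]].astype(float)
    frames = np.empty((nf, h, w), np.uint8)
    for i in range(nf):
        frame = background + rng.standard_normal((h, w)) * cfg.video_noise_sd
        dy = breath_trace[i] if i < len(breath_trace) else 0.0
        patch = map_coordinates(rib_tex, [yy_r + dy, xx_r], order=1,
                                mode="nearest")
        x, y, rw, rh = rib_rect
        frame[y:y + rh, x:x + rw] += patch
        patch = map_coordinates(eye_tex, [yy_e, xx_e + eye_offset[i]],
                                order=1, mode="nearest")
        x, y, rw, rh = eye_rect
        frame[y:y + rh, x:x + rw] += patch
        frames[i] = np.clip(frame, 0, 255).astype(np.uint8)
    return frames, rib_rect, eye_rect


# ---------------------------------------------------------------------------
# full recording

def generate_recording(cfg: GenConfig):
    """Bundle all channels of one synthetic night.

    Deterministic: identical ``GenConfig`` (including seed) yields
    bit-identical output.  Returns ``(Recording, GroundTruth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    intervals, cycle_starts, cycle_periods = synth_state_sequence(cfg, rng)
    lfp, shw_times = synth_lfp(cfg, intervals, rng)
    twitches = synth_phase_locked_events(
        cfg, cycle_starts, cycle_periods,
        cfg.twitch_rate_per_cycle, cfg.twitch_phase_rad, cfg.twitch_kappa, rng)
    eyes = synth_phase_locked_events(
        cfg, cycle_starts, cycle_periods,
        cfg.eye_event_rate_per_cycle, cfg.eye_phase_rad, cfg.eye_kappa, rng)
    spikes = _synth_spikes(cfg, intervals, shw_times, rng)
    accel, breath, inst_rate = synth_accel_breath(cfg, intervals, twitches, rng)

    t_log = np.arange(0, cfg.duration_s, 1.0)
    temp = cfg.temperature_c + 0.1 * rng.standard_normal(len(t_log))

    video = None
    if cfg.video_fps > 0:
        step = max(int(round(cfg.accel_rate_hz / cfg.video_fps)), 1)
        video, _, _ = synth_video(cfg, breath[::step], eyes, rng)

    rec = Recording(
        lfp=lfp[np.newaxis, :],
        lfp_rate_hz=cfg.lfp_rate_hz,
        accel=accel,
        accel_rate_hz=cfg.accel_rate_hz,
        temperature_time_s=t_log,
        temperature_c=temp,
        spike_times_s=spikes,
        breath_displacement=breath,
        breath_displacement_rate_hz=cfg.accel_rate_hz,
        video=video,
        video_fps=cfg.video_fps,
        seed=cfg.seed,
    )
    truth = GroundTruth(
        state_intervals=intervals,
        cycle_starts_s=cycle_starts,
        cycle_periods_s=cycle_periods,
        shw_times_s=shw_times,
        twitch_times_s=twitches,
        eye_times_s=eyes,
        spike_times_s=spikes,
        breath_rate_hz=inst_rate,
        cycle_period_s=cfg.cycle_period_s,
    )
    return rec, truth
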