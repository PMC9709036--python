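"""Population spiking across sleep states.

Multi-unit analysis: threshold spike extraction from the wide-band trace,
binned rate series, state-conditioned rate distributions with Pearson
kurtosis (normal = 3), and circular phase locking of the rate to the
delta/beta cycle.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

from .spectral import LfpSignal
from .cycles import CycleSet, cycle_phase, phase_average

__all__ = [
    "detect_spikes",
    "rate_series",
    "state_rate_stats",
    "rate_phase_locking",
]


def detect_spikes(sig: LfpSignal, highpass_hz: float = 300.0,
                  thresh_sd: float = 5.0, refractory_s: float = 0.001) -> np.ndarray:
    """Negative threshold crossings of the high-passed trace.

    The noise scale is the robust SD (MAD/0.6745) of the filtered trace;
    spikes are peaks below ``-thresh_sd`` noise SDs with a 1-ms
    refractory.  Returns spike times in seconds.
    """
    if sig.rate < 2 * highpass_hz:
        raise ValueError(f"rate {sig.rate} Hz too low for a {highpass_hz}-Hz high-pass")
    if len(sig.samples) == 0:
        return np.array([])
    sos = signal.butter(4, highpass_hz, "highpass", fs=sig.rate, output="sos")
    x = signal.sosfiltfilt(sos, sig.samples)
    noise_sd = np.median(np.abs(x)) / 0.6745
    dist = max(int(round(refractory_s * sig.rate)), 1)
    peaks, _ = signal.find_peaks(-x, height=thresh_sd * noise_sd, distance=dist)
    return peaks / sig.rate + sig.t0


def rate_series(spike_times_s, bin_s: float, t_start: float = 0.0,
                t_end: float | None = None):
    """Binned firing rate (Hz).  Returns ``(bin_centers_s, rate_hz)``."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    t = np.asarray(spike_times_s, float)
    if t_end is None:
        t_end = t.max() + bin_s if len(t) else bin_s
    edges = np.arange(t_start, t_end + bin_s * 0.5, bin_s)
    counts, _ = np.histogram(t, edges)
    return edges[:-1] + bin_s / 2, counts / bin_s


def state_rate_stats(rate_times_s, rate_hz, cycles: CycleSet,
                     min_bins: int = 50):
    """Rate distributions and Pearson kurtosis within SWS and REM.

    Bins are assigned to the state segment of the kept cycle containing
    them (REM between the REM and SWS onsets, SWS for the remainder of the
    cycle).  Kurtosis is the non-excess (Pearson) moment ratio, so a
    normal distribution scores 3.  Returns a dict.
    """
    rate_times_s = np.asarray(rate_times_s, float)
    rate_hz = np.asarray(rate_hz, float)
    sws_rates, rem_rates = [], []
    for i in np.nonzero(cycles.kept)[0]:
        r0, r1 = cycles.rem_onsets_s[i], cycles.rem_onsets_s[i + 1]
        s0 = cycles.sws_onsets_s[i]
        rem_rates.append(rate_hz[(rate_times_s >= r0) & (rate_times_s < s0)])
        sws_rates.append(rate_hz[(rate_times_s >= s0) & (rate_times_s < r1)])
    sws = np.concatenate(sws_rates) if sws_rates else np.array([])
    rem = np.concatenate(rem_rates) if rem_rates else np.array([])
    if len(sws) < min_bins or len(rem) < min_bins:
        raise ValueError(f"need >= {min_bins} rate bins per state")
    if np.ptp(sws) == 0 or np.ptp(rem) == 0:
        raise ValueError("constant rate: kurtosis undefined")
    return {
        "sws_rates": sws,
        "rem_rates": rem,
        "kurtosis_sws": float(stats.kurtosis(sws, fisher=False)),
        "kurtosis_rem": float(stats.kurtosis(rem, fisher=False)),
        "mean_sws": float(sws.mean()),
        "mean_rem": float(rem.mean()),
    }


def rate_phase_locking(rate_times_s, rate_hz, cycles: CycleSet,
                       min_cycles: int = 10, nbins: int = 36):
    """Circular mean phase and peak phase of the rate over the cycle.

    The mean phase is the rate-weighted circular mean of the bin phases;
    the peak phase is the argmax of the phase-average curve.  The result
    is flagged non-significant when the resultant length is small.
    Returns a dict.
    """
    if cycles.n_kept < min_cycles:
        raise ValueError(f"need >= {min_cycles} kept cycles")
    rate_times_s = np.asarray(rate_times_s, float)
    rate_hz = np.asarray(rate_hz, float)
    ph = cycle_phase(rate_times_s, cycles)
    ok = np.isfinite(ph) & (rate_hz >= 0)
    if rate_hz[ok].sum() == 0:
        raise ValueError("zero total rate inside kept cycles")
    z = np.sum(rate_hz[ok] * np.exp(1j * ph[ok])) / rate_hz[ok].sum()
    mean_phase = float(np.mod(np.angle(z), 2 * np.pi))
    resultant = float(np.abs(z))
    try:
        phases, curve, _ = phase_average(rate_times_s, rate_hz, cycles,
                                         nbins=nbins, min_cycles=min_cycles)
        peak_phase = float(phases[np.argmax(curve)])
    except ValueError:   # rate flat or too sparse for a phase profile
        peak_phase = np.nan
    return {
        "mean_phase_rad": mean_phase,
        "peak_phase_rad": peak_phase,
        "resultant_length": resultant,
        "significant": resultant >= 0.05,
    }
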