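"""LFP spectral pipeline: preprocessing, binned Welch spectra, two-state
clustering, transition frequency, and the delta/beta ratio series.

The delta/beta ratio — mean per-Hz power below 4 Hz over mean per-Hz power
between 10 and 40 Hz, measured in 10-s trailing windows stepped by 1 s —
is the central object of the downstream cycle analysis: it is high during
slow-wave-like sleep and low during REM-like sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "LfpSignal",
    "SpectrumBins",
    "StateClustering",
    "DeltaBetaSeries",
    "preprocess_lfp",
    "binned_spectra",
    "cluster_spectral_states",
    "transition_frequency",
    "delta_beta_series",
]


@dataclass
class LfpSignal:
    samples: np.ndarray   # microvolts
    rate: float           # Hz
    t0: float = 0.0       # seconds

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP contains non-finite samples")


@dataclass
class SpectrumBins:
    bin_start_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray        # (bins, freqs), uV^2/Hz
    norm_power: np.ndarray   # power / per-frequency dataset mean


@dataclass
class StateClustering:
    labels: np.ndarray        # per bin, 0 = higher delta-band power
    mean_spectra: np.ndarray  # (2, freqs), normalized
    freqs_hz: np.ndarray
    f_trans_hz: float


@dataclass
class DeltaBetaSeries:
    times_s: np.ndarray   # window end times, 1-s step
    values: np.ndarray
    window_s: float = 10.0

    def __post_init__(self):
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def step_s(self) -> float:
        return float(np.median(np.diff(self.times_s))) if len(self.times_s) > 1 else 1.0


def preprocess_lfp(sig: LfpSignal, lowpass_hz: float = 100.0,
                   out_rate_hz: float = 200.0) -> LfpSignal:
    """Zero-phase low-pass (4th-order Butterworth) and downsample.

    Matches the standard preprocessing of reptile sleep LFP: 100-Hz
    low-pass, 200-Hz output rate.  Integer decimation uses plain slicing
    (anti-aliasing comes from the low-pass); non-integer ratios go through
    a polyphase resampler with edge padding.
    """
    if sig.rate < 2 * lowpass_hz:
        raise ValueError(
            f"input rate {sig.rate} Hz too low; need >= {2 * lowpass_hz} Hz "
            f"for a {lowpass_hz}-Hz low-pass")
    sos = signal.butter(4, lowpass_hz, "lowpass", fs=sig.rate, output="sos")
    x = signal.sosfiltfilt(sos, sig.samples)
    ratio = sig.rate / out_rate_hz
    if abs(ratio - round(ratio)) < 1e-9:
        y = x[:: int(round(ratio))]
    else:
        from fractions import Fraction
        frac = Fraction(out_rate_hz / sig.rate).limit_denominator(1000)
        y = signal.resample_poly(x, frac.numerator, frac.denominator,
                                 padtype="line")
    return LfpSignal(y, out_rate_hz, sig.t0)


def _segment_psds(x, fs, welch_win_s=1.0, overlap=0.5):
    """Per-segment modified periodograms (Hann), the Welch building block.

    Returns (segment start times, freqs, psd (segments, freqs)).
    """
    nper = int(round(welch_win_s * fs))
    hop = max(int(round(nper * (1 - overlap))), 1)
    if len(x) < nper:
        raise ValueError("signal shorter than one Welch window")
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper - hop,
        scaling="density", mode="psd", detrend="constant")
    starts = times - welch_win_s / 2.0
    return starts, freqs, sxx.T


def binned_spectra(sig: LfpSignal, bin_s: float = 10.0,
                   welch_win_s: float = 1.0, overlap: float = 0.5) -> SpectrumBins:
    """Welch PSD per consecutive bin, plus per-frequency normalized power.

    Each bin's spectrum is the mean periodogram over the 1-s, 50%-overlap
    segments wholly contained in the bin; the normalized spectrum divides
    each frequency by its mean over all bins (so the per-frequency mean of
    ``norm_power`` is 1).  A trailing partial bin is dropped.
    """
    if len(sig.samples) == 0:
        raise ValueError("empty signal")
    starts, freqs, psd = _segment_psds(sig.samples, sig.rate, welch_win_s, overlap)
    n_bins = int(len(sig.samples) / sig.rate // bin_s)
    if n_bins == 0:
        raise ValueError("signal shorter than one bin")
    bin_start = np.arange(n_bins) * bin_s
    power = np.empty((n_bins, len(freqs)))
    for b, s0 in enumerate(bin_start):
        m = (starts >= s0 - 1e-9) & (starts + welch_win_s <= s0 + bin_s + 1e-9)
        power[b] = psd[m].mean(axis=0)
    mean_spec = power.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(mean_spec > 0, power / mean_spec, 0.0)
    return SpectrumBins(bin_start + sig.t0, freqs, power, norm)


def cluster_spectral_states(bins: SpectrumBins, fmax_hz: float = 30.0) -> StateClustering:
    """Split spectrum bins into two states by Ward clustering.

    The features are the rows of the bin-by-bin Pearson correlation
    matrix of the log-scaled normalized spectra (restricted to
    frequencies up to ``fmax_hz``); correlating log profiles keeps the
    weaker band's structure from being swamped by the dominant band.
    The Ward dendrogram is cut at two clusters; cluster 0 is the one
    with higher mean delta-band (<4 Hz) normalized power, so labels are
    comparable across nights.
    """
    fsel = (bins.freqs_hz > 0) & (bins.freqs_hz <= fmax_hz)
    feats = np.log10(np.maximum(bins.norm_power[:, fsel], 1e-12))
    if feats.shape[0] < 4:
        raise ValueError("need at least 4 bins to cluster")
    sd = feats.std(axis=1)
    if np.any(sd == 0) or np.allclose(feats, feats[0]):
        raise ValueError("degenerate clustering: bins have no spectral contrast")
    corr = np.corrcoef(feats)
    z = linkage(corr, method="ward")
    labels = fcluster(z, 2, criterion="maxclust") - 1
    if labels.min() == labels.max():
        raise ValueError("degenerate clustering: only one cluster found")

    dsel = (bins.freqs_hz > 0) & (bins.freqs_hz < 4.0)
    d0 = bins.norm_power[labels == 0][:, dsel].mean()
    d1 = bins.norm_power[labels == 1][:, dsel].mean()
    if d1 > d0:
        labels = 1 - labels
    mean_spectra = np.vstack([
        bins.norm_power[labels == 0].mean(axis=0),
        bins.norm_power[labels == 1].mean(axis=0),
    ])
    clus = StateClustering(labels, mean_spectra, bins.freqs_hz, np.nan)
    clus.f_trans_hz = transition_frequency(clus, fmax_hz=fmax_hz)
    return clus


def transition_frequency(clustering: StateClustering, fmin_hz: float = 0.5,
                         fmax_hz: float = 30.0) -> float:
    """Frequency where the two mean normalized spectra cross.

    Linear interpolation between adjacent frequency samples; if several
    crossings exist, the lowest one above ``fmin_hz`` is returned (the
    physiological delta-to-beta crossover is the low-frequency one).
    """
    f = clustering.freqs_hz
    diff = clustering.mean_spectra[0] - clustering.mean_spectra[1]
    m = (f >= fmin_hz) & (f <= fmax_hz)
    idx = np.nonzero(m)[0]
    if np.allclose(diff[idx], 0):
        raise ValueError("identical mean spectra: no crossing")
    for i, j in zip(idx[:-1], idx[1:]):
        if diff[i] == 0:
            return float(f[i])
        if diff[i] * diff[j] < 0:
            return float(f[i] + (f[j] - f[i]) * diff[i] / (diff[i] - diff[j]))
    raise ValueError(f"no spectral crossing in ({fmin_hz}, {fmax_hz}] Hz")


def delta_beta_series(sig: LfpSignal, win_s: float = 10.0, step_s: float = 1.0,
                      delta=(0.0, 4.0), beta=(10.0, 40.0)) -> DeltaBetaSeries:
    """Delta/beta power ratio over trailing windows.

    Per step, the Welch spectrum of the trailing ``win_s`` window is
    reduced to mean per-Hz power below ``delta[1]`` (the 0-Hz DC sample is
    excluded) divided by mean per-Hz power in the closed ``beta`` band.
    Timestamps mark window ends.  Windows with zero beta-band power map
    to +inf.
    """
    if sig.rate < 2 * beta[1]:
        raise ValueError(f"rate {sig.rate} Hz cannot resolve the beta band")
    starts, freqs, psd = _segment_psds(sig.samples, sig.rate)
    dsel = (freqs > delta[0]) & (freqs < delta[1])
    bsel = (freqs >= beta[0]) & (freqs <= beta[1])
    dpow = psd[:, dsel].mean(axis=1)
    bpow = psd[:, bsel].mean(axis=1)

    duration = len(sig.samples) / sig.rate
    ends = np.arange(win_s, duration + 1e-9, step_s)
    values = np.empty(len(ends))
    for k, te in enumerate(ends):
        m = (starts >= te - win_s - 1e-9) & (starts + 1.0 <= te + 1e-9)
        d, b = dpow[m].mean(), bpow[m].mean()
        values[k] = np.inf if b == 0 else d / b
    return DeltaBetaSeries(ends + sig.t0, values, win_s)
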