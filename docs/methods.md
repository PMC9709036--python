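# Methods

This note documents the models and procedures the package implements,
the synthetic data they are validated on, and the numerical and design
choices made where the problem left room.

## State variable and spectral machinery

The LFP is low-pass filtered at 100 Hz with a 4th-order zero-phase
Butterworth (forward–backward), then downsampled to 200 Hz (plain
decimation for integer ratios — the low-pass is the anti-alias filter —
and a linear-phase polyphase resampler with edge padding otherwise).

All spectra derive from one building block: modified periodograms of
1-s Hann windows with 50% overlap (`scipy.signal.spectrogram`,
density scaling). A 10-s bin's Welch spectrum is the mean over the 19
segments wholly inside the bin; the δ/β ratio at time t is the mean
per-Hz power at 0 < f < 4 Hz divided by the mean per-Hz power at
10 ≤ f ≤ 40 Hz over the trailing 10-s window, timestamped at the
window end and stepped by 1 s. The DC bin is excluded from the δ band
so electrode offset cannot dominate. A window with zero β power maps
to +inf and is flagged rather than dropped.

Two-state clustering: normalized spectra (each frequency divided by its
dataset mean, so the per-frequency mean over bins is exactly 1) are
log10-scaled, restricted to 0–30 Hz, and the rows of their bin–bin
Pearson correlation matrix are clustered by Ward linkage cut at two.
The log scaling matters: in linear units the normalization whitens the
dominant class's own contrast, leaving its profiles nearly flat and its
bin–bin correlations noise-dominated; log profiles keep both bands'
structure and make the split exact on unambiguous bins. Cluster 0 is
canonically the one with higher mean normalized δ power. The transition
frequency is the lowest crossing (above 0.5 Hz, linear interpolation
between frequency samples) of the two mean normalized spectra; the
low-frequency crossover is the physiological one when harmonic
crossings exist at higher frequencies.

## Cycle statistics

The autocorrelation is the biased normalized estimator on the demeaned
series; its white-noise 95% bound is 1.96/√N. The oscillation period is
the lag of the first local maximum after the first zero crossing
(avoiding the shoulder at small lags), the anti-phase lag the first
local minimum, both required to have prominence at least the confidence
bound; P2V = peak − valley − 2·bound, floored at 0. A series with no
qualifying extrema yields a "no oscillation" result rather than an
error.

Sleep detection computes a floating autocorrelation (1000-s bins, 100-s
steps, autocorrelation smoothed by a 10-s moving average, extrema
searched within ±20 s of the global period and anti-phase lag); bins
with P2V > 0.25 are sleep, the boolean series is majority-filtered over
1 h (mean ≥ 0.5 — identical to a median for booleans), and the longest
run is the sleep interval. The per-night period and P2V are then
re-estimated on the 2-h window with the highest local P2V (earliest on
ties).

Cycle segmentation median-filters the δ/β (20-s window, edge
replication, odd kernel), demeans, Hilbert-transforms, and takes the
peaks of the wrapped instantaneous phase as REM onsets; the SWS onset
inside each cycle is the minimum of the quadrature component of the
analytic signal, which for a near-sinusoidal δ/β is its rising zero
crossing. Cycles longer than 1.5× or shorter than 1/1.5× the mean
duration are flagged and excluded from phase analyses. Two geometric
consequences of these (standard) landmark definitions are worth
stating, because they are properties of the method and visible on
surrogate data:

- the phase-peak landmark sits at the δ/β trough, i.e. near the middle
  of the low-δ/β span, a constant ~0.2 cycle after the moment the
  spectral content actually switches. All phase-locking results are
  therefore reported relative to the δ/β circular mean phase, in which
  frame the constant offset cancels;
- the REM-onset-to-quadrature-minimum segment spans about a quarter
  cycle for a near-sinusoidal δ/β, so the detected SWS/REM duration
  ratio is ≈ 3 for a symmetric oscillation and should be read as a
  relative, not generative, quantity.

The robust CV of cycle durations is 1.4826·MAD/median (the 1.4826
factor makes MAD a consistent σ estimator under normality); the field's
"robust coefficient of variation" has no single definition, and this is
the one adopted here.

## Sharp waves

The template is a unit-peak, zero-mean average of curated event
snippets at 400 Hz; the packaged default is a biphasic difference of
Gaussians (narrow negative core, σ = width/2.355; broad positive
surround at 2σ, weight 0.55) — real averaged sharp waves are biphasic
but no analytic form is canonical. Detection anti-alias filters at
160 Hz and resamples to 400 Hz (a literal "400-Hz low-pass then 400-Hz
resampling" would fold the band above Nyquist), whitens the trace by
its own Welch PSD, and correlates with the equally whitened template.
The score is the per-sample least-squares amplitude estimate divided by
a reference amplitude, so a clean template occurrence at the reference
amplitude scores 1 and the threshold is a fraction of that amplitude.
Whitening is essential: the δ-band background correlates with the
template, and an energy-normalized (cosine) matched filter fails
(F1 < 0.4 at SNR 5) where the whitened one is near-perfect (F1 ≈ 0.99).
One template length at each trace edge is blanked (circular-correlation
wrap-around). Events are score peaks above threshold with a 100-ms
refractory; events whose raw amplitude exceeds 1 mV are discarded as
artifacts. The threshold is calibrated by F1 optimization over a
labeled set (ties to the higher threshold); the pipeline default of
0.88 is the calibration result on labeled synthetic nights at default
conditions (per-night optima 0.82–0.91, F1 ≈ 0.97).

Morphology is measured on the 40-Hz low-passed trace: amplitude is the
peak deviation from the local median baseline in a ±0.5-s window, width
the full width at half maximum around that peak; edge events are
skipped and logged. Note the width parameter of the synthetic kernel is
the Gaussian-core FWHM; the realized FWHM of the biphasic composite is
smaller (the surround subtracts from the shoulders), so only relative
width comparisons across temperatures are meaningful. Ripple analysis
band-passes 60–200 Hz (4th-order Butterworth, zero-phase), takes the
Hilbert envelope, and averages event-triggered windows; the
event-triggered Morlet scalogram (PyWavelets, 40–250 Hz log-spaced)
is computed on the mean triggered waveform. Nights with P2V < 0.2 or
wide-band power < 40 dB (re 1 µV²) are excluded; boundary values are
included.

In the night pipeline the sharp-wave rate is binned at 1.2 s and its
oscillation period read from the smoothed (10-s) autocorrelation peak
within ±20 s of the global δ/β period — the same anchored search the
sleep detector uses, justified by the rate's locking to the cycle.

## Spikes, behavior, circular statistics

Spike extraction (when no spike times are supplied) is a negative
threshold at 5 robust SDs (MAD/0.6745) of the 300-Hz high-passed trace
with 1-ms refractory — multi-unit, deliberately: all analyses concern
the population rate. State-conditioned rate distributions use Pearson
(non-excess) kurtosis, normal = 3. The rate's mean phase is the
rate-weighted circular mean of bin phases; its peak phase the argmax of
the cycle-phase-resampled average (each kept cycle linearly resampled
onto 36 phase bins, averaged, min–max normalized).

Micro-movements: axes decimated to 250 Hz (Chebyshev), upper-minus-
lower spline envelope over local extrema (extrema at least 40 ms apart,
so the envelope follows transient oscillations rather than every noise
wiggle), summed over axes and smoothed over 60 ms; the noise level is
estimated only on 2-s bins with Pearson kurtosis ≤ 3, and events are
crossings of mean + 4 SD, timestamped at their peak. On pure Gaussian
noise this yields ≲ 1 event/min; 10-SD oscillatory transients are all
recovered.

Breathing: corner points (Shi–Tomasi minimum-eigenvalue measure,
scikit-image) inside the ribcage rectangle are tracked by an in-house
vectorized Lucas–Kanade step (7-px windows, 3 iterations, bilinear
sampling), re-detected every 100 s or when fewer than 40 points or a
>10% drop survive; re-detection frames are excluded. The per-frame mean
position, median-filtered over 2 s, is reduced by PCA; PC1 (sign chosen
so the dominant-axis loading is positive) is the respiration trace.
The global peak lag GP comes from the whole-trace autocorrelation;
each 24-s window (50% overlap) contributes rate = 1/lag of its first
prominent autocorrelation peak within [GP−2.5 s, GP+5 s] (prominence
at least 2/√N, the white-noise wiggle scale — windows without a
qualifying peak, or whose deepest pre-limit valley lies beyond the
peak, are rejected; on white noise most windows are). Amplitude is the
per-window peak-to-trough of the (already median-filtered) trace; this
is an interpretation — the original analyses define only the rate.

Eye movements: dense Lucas–Kanade flow (windowed gradient least
squares, solved per pixel) between consecutive 5-Hz frames inside the
eye rectangle (5-px border excluded); the rectangle follows the
accumulated median flow, moving only when the candidate deviates by
more than 25% of the width or height in that dimension, checked at
0.6 Hz; frames with fewer than 3 well-conditioned pixels are flagged.
Events exceed a floating threshold of 6 MADs above the 3-min rolling
median. Surrogate controls redraw each cycle's event times uniformly
over that cycle, preserving per-cycle counts exactly.

Circular statistics use `scipy.stats.circmean` conventions and
pingouin's Rayleigh test; event phases come from the cycle clock
(phase 0 at the detected REM onset, linear in time), and all reported
mean phases are relative to the δ/β-weighted circular mean phase.
Co-occurrence of two event sources is the fraction of one source's
events within 1 s (configurable) of the other's, with Pearson
correlation of co-occurring amplitudes and the maximum normalized
cross-correlation of the underlying traces over ±10 s. Significance is
α = 0.05 throughout, uncorrected.

## Temperature scaling

Q10 fits are nonlinear least squares of R(T) = R(T0)·Q10^((T−T0)/10)
on per-night rates (cycles/min) against the night's median logged
temperature, initialized from the log-linear regression. T0 defaults to
17 °C (a 18 °C convention also circulates); the fitted Q10 is invariant
to T0 — only the reference rate rescales — and a test asserts this.
Power and center-of-mass correlations use per-animal normalization
(each night's 0–30 Hz PSD sum divided by that animal's mean) and the
correlation t-test t = r√((n−2)/(1−r²)); sharp-wave widths are
z-scored per animal before pooling. The CV-vs-temperature comparison
fits degree-1 and degree-2 polynomials by OLS and reports each model's
F-test against the constant model.

## The synthetic generator: what it emulates, and what not

One night is assembled from a seeded `numpy` Generator, so identical
configurations are bit-identical. Cycles tile the sleep span
(optionally inside quiescent wake margins) with lognormal duration
jitter (CV 0.1; mean-preserving) around the Q10-scaled period; each
cycle is an SWS span (fraction 0.55) then a REM span. Defaults place
the reference period at 213.4 s at 17 °C with Q10 = 2.3, i.e. 92.8 s
at 27 °C — the center of the observed nightly range.

The LFP mixes a <4-Hz low-pass kernel and a 6–40-Hz band kernel
(order-2 low edge, so the state spectra cross a few Hz above the δ
band, as real spectra do). Each state keeps a residual of the opposite
kernel (β residual 0.3 in SWS, δ residual 0.08 in REM): real spectra
never vanish in the opposite band, and without the residuals the δ/β
ratio spans five decades and its autocorrelation becomes erratically
heavy-tail dominated. Amplitudes sit on the real recording scale
(SWS 120 µV RMS; wide-band power above the 40-dB quality floor).
Sharp waves are Poisson in SWS (0.4 Hz, 300-ms minimum separation,
rarely in REM), each a difference-of-Gaussians transient (450 µV,
120-ms core) with a Gaussian-windowed 100-Hz ripple at its trough;
width shrinks and power grows with temperature (1 + 0.03/°C and
1 + 0.05/°C respectively), emulating the observed morphology trends.
Spiking is tonic Poisson in REM (20 Hz) versus sparse SWS spiking
(2 Hz) plus bursts riding sharp waves — hence heavy-tailed SWS rate
distributions. Twitches and eye events are per-cycle Poisson counts
with von Mises phases (κ = 6, means in the REM half-cycle); breathing
is a phase-continuous sinusoid at 0.12 Hz (SWS) / 0.25 Hz (REM) with
1.5× REM amplitude — slow enough to survive the 2-s median filter in
the video chain; video renders speckle-textured ribcage and eye patches
(sub-pixel translation for breathing; persistent alternating 3-px jumps
at eye events, so each event is one flow transient) over a static noisy
background.

Passing tests on these surrogates show the chain recovers what the
generator put in, under the stated noise; they do not certify
performance on real data with electrode artifacts, non-stationary
backgrounds, fragmented sleep, animal locomotion, or video occlusions —
none of which the generator emulates.

## Problem sizes and evaluation conventions

Validation nights are 3600 s (the analysis-relevant content of a night:
30–75 cycles depending on temperature); the video chain is validated on
600-s, 10-fps, 96×96 clips with ~60-s cycles so that ten full cycles
fit. The clustering benchmark scores only bins lying wholly inside one
state: a 10-s bin straddling a transition has no defined state, and its
label measures bin-boundary phase rather than the classifier (with ~9
bins per cycle such coin-flip bins alone would cap the achievable
bin-center-labeled agreement below any useful threshold). Event-
recovery comparisons match detections to ground truth greedily within
±12.5 ms (sharp waves) or stated tolerances. Shuffled-control
significance is summarized by the median Rayleigh p over 20 independent
per-cycle shuffles, whose sampling distribution under the null is
concentrated near 0.5.
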