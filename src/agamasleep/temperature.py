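"""Temperature scaling of sleep dynamics: Q10/Arrhenius fits and
across-night temperature correlations.

The core model is the Q10 temperature coefficient rule

    R(T) = R(T0) * q10 ** ((T - T0) / 10)

fitted by nonlinear least squares to per-night oscillation rates
(cycles/min) against the night's median ambient temperature.  Q10 is
invariant to the choice of T0 (only the reference rate changes).
Per-night summary rows feed the correlation analyses: normalized PSD sum,
spectral center of mass, SWS/REM duration ratio, ShW width, and the
robust CV of cycle durations (linear vs quadratic temperature fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Q10Fit",
    "NightSummary",
    "fit_q10",
    "arrhenius_predict",
    "correlation_ttest",
    "normalized_power_correlation",
    "psd_center_of_mass",
    "com_correlation",
    "state_duration_ratio",
    "shw_temperature_suite",
    "cv_temperature_fit",
]


@dataclass
class Q10Fit:
    f0: float          # rate at T0
    q10: float
    t0_c: float
    residual_ss: float
    n_nights: int
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.q10 <= 0 or self.f0 <= 0:
            raise ValueError("Q10 and F0 must be positive")


@dataclass
class NightSummary:
    """One row per analyzed night."""
    animal_id: str = ""
    night_id: str = ""
    median_temp_c: float = np.nan
    period_s: float = np.nan
    p2v: float = np.nan
    sleep_start_s: float = np.nan
    sleep_end_s: float = np.nan
    psd_sum: float = np.nan
    psd_com_hz: float = np.nan
    f_trans_hz: float = np.nan
    sws_rem_ratio: float = np.nan
    shw_rate_period_s: float = np.nan
    shw_width_ms: float = np.nan
    shw_amp_uv: float = np.nan
    cycle_cv: float = np.nan
    n_cycles: int = 0
    included: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def fit_q10(temps_c, rates, t0_c: float = 17.0) -> Q10Fit:
    """Least-squares Q10 fit of rates against temperature.

    ``rates`` may be in any consistent unit (cycles/min is conventional).
    Requires at least two distinct temperatures.
    """
    t = np.asarray(temps_c, float)
    r = np.asarray(rates, float)
    ok = np.isfinite(t) & np.isfinite(r)
    t, r = t[ok], r[ok]
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct temperatures")

    def model(tt, f0, q10):
        return f0 * q10 ** ((tt - t0_c) / 10.0)

    # closed-form initialization from the log-linear regression
    slope, intercept = np.polyfit(t - t0_c, np.log(np.maximum(r, 1e-12)), 1)
    p0 = (float(np.exp(intercept)), float(np.exp(10 * slope)))
    popt, _ = optimize.curve_fit(model, t, r, p0=p0,
                                 bounds=([1e-12, 1e-6], [np.inf, np.inf]),
                                 maxfev=20000)
    resid = r - model(t, *popt)
    return Q10Fit(float(popt[0]), float(popt[1]), t0_c,
                  float(np.sum(resid ** 2)), len(r), resid)


def arrhenius_predict(fit: Q10Fit, temp_c) -> np.ndarray | float:
    """Rate predicted by a Q10 fit at the given temperature(s)."""
    return fit.f0 * fit.q10 ** ((np.asarray(temp_c, float) - fit.t0_c) / 10.0)


def correlation_ttest(x, y):
    """Pearson r with the two-sided t-test t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def normalized_power_correlation(nights: pd.DataFrame):
    """Temperature correlation of the per-animal-normalized PSD sum.

    Each night's 0-30 Hz PSD sum is divided by its animal's mean over
    nights; the pooled Pearson r against median temperature is tested
    with the correlation t-test.  Returns ``(r, p, normalized_sums)``.
    """
    df = nights.dropna(subset=["psd_sum", "median_temp_c"])
    per_animal = df.groupby("animal_id")["psd_sum"].transform("mean")
    if df.groupby("animal_id").size().max() < 2 and df["animal_id"].nunique() < 2:
        raise ValueError("need multiple nights (or animals) to normalize")
    norm = df["psd_sum"] / per_animal
    r, p = correlation_ttest(df["median_temp_c"], norm)
    return r, p, norm.to_numpy()


def psd_center_of_mass(freqs_hz, psd, fmax_hz: float = 30.0) -> float:
    """Spectral center of mass sum(f P(f)) / sum(P(f)) up to ``fmax_hz``."""
    f = np.asarray(freqs_hz, float)
    p = np.asarray(psd, float)
    m = (f >= 0) & (f <= fmax_hz)
    tot = p[m].sum()
    if tot <= 0:
        raise ValueError("non-positive total power")
    return float(np.sum(f[m] * p[m]) / tot)


def com_correlation(nights: pd.DataFrame):
    """Temperature correlation of the per-night spectral center of mass."""
    df = nights.dropna(subset=["psd_com_hz", "median_temp_c"])
    return correlation_ttest(df["median_temp_c"], df["psd_com_hz"])


def state_duration_ratio(cycles) -> float:
    """Total SWS duration over total REM duration within kept cycles.

    The REM segment of a cycle runs from its REM onset to its SWS onset;
    the rest is SWS.
    """
    rem = sws = 0.0
    for i in np.nonzero(cycles.kept)[0]:
        r0, r1 = cycles.rem_onsets_s[i], cycles.rem_onsets_s[i + 1]
        s0 = cycles.sws_onsets_s[i]
        rem += s0 - r0
        sws += r1 - s0
    if rem == 0:
        raise ValueError("no REM time in kept cycles")
    return float(sws / rem)


def shw_temperature_suite(nights: pd.DataFrame, t0_c: float = 17.0):
    """ShW temperature analyses: rate-period Q10 fit and the width trend.

    The Q10 fit uses the per-night ShW oscillation period (converted to
    cycles/min); the width correlation is computed on per-animal z-scored
    widths.  Returns a dict.
    """
    from .shw import zscore_by_group
    df = nights.dropna(subset=["shw_rate_period_s", "median_temp_c"])
    fit = fit_q10(df["median_temp_c"], 60.0 / df["shw_rate_period_s"], t0_c)
    dfw = nights.dropna(subset=["shw_width_ms", "median_temp_c"])
    zw = zscore_by_group(dfw["shw_width_ms"].to_numpy(),
                         dfw["animal_id"].to_numpy())
    r, p = correlation_ttest(dfw["median_temp_c"], zw)
    return {"rate_q10_fit": fit, "width_r": r, "width_p": p, "width_z": zw}


def cv_temperature_fit(temps_c, cvs):
    """Linear and quadratic OLS fits of cycle-duration CV vs temperature.

    Each polynomial model is compared against the constant model with an
    F-test; returns a dict with coefficients, R^2 and p per degree.
    """
    t = np.asarray(temps_c, float)
    c = np.asarray(cvs, float)
    ok = np.isfinite(t) & np.isfinite(c)
    t, c = t[ok], c[ok]
    if len(t) < 5 or len(np.unique(t)) < 3:
        raise ValueError("need >= 5 nights spanning >= 3 temperatures")
    out = {}
    ss_tot = np.sum((c - c.mean()) ** 2)
    for deg, name in ((1, "linear"), (2, "quadratic")):
        if len(np.unique(t)) <= deg:
            raise ValueError("rank-deficient design for the polynomial fit")
        coef = np.polyfit(t, c, deg)
        pred = np.polyval(coef, t)
        ss_res = np.sum((c - pred) ** 2)
        df1, df2 = deg, len(t) - deg - 1
        if ss_res <= 0:
            fstat, pval = np.inf, 0.0
        else:
            fstat = ((ss_tot - ss_res) / df1) / (ss_res / df2)
            pval = float(stats.f.sf(fstat, df1, df2))
        out[name] = {
            "coef": coef,
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
            "f_stat": float(fstat),
            "p_value": pval,
        }
    return out
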