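"""Oscillation statistics of stochastic limit-cycle trajectories.

Peak-time bookkeeping across an ensemble gives the period and the peak-time
diffusion constant (the slope of the linear growth of the i-th peak-time
variance with its mean); the phase diffusion constant follows as
D_phi = D_peak (2 pi)^2 / (2 T). The autocorrelation of a noisy oscillator
decays as exp(-t/tau_c) cos(2 pi t / T), with tau_c the coherence time, and
its Fourier transform pairs with the power spectral density. The phase
coherence xi in [-1, 1] measures the persistence of the rotation direction
around a center: +1 for a deterministic counterclockwise cycle, -1 for the
time-reversed cycle, ~0 for direction-less diffusion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, welch

__all__ = [
    "PeakTable",
    "OscillationStats",
    "AutocorrResult",
    "SpectrumResult",
    "CoherenceResult",
    "detect_peaks",
    "peak_time_statistics",
    "phase_diffusion",
    "autocorrelation",
    "autocorrelation_fit",
    "fit_autocorrelation_curve",
    "power_spectrum",
    "average_power_spectrum",
    "ensemble_autocorrelation_fit",
    "phase_coherence",
]


@dataclass
class PeakTable:
    """Ordered peak times of one trajectory's chosen coordinate."""

    peak_times: np.ndarray
    smoothing_window: int
    component: int = 0
    peak_values: np.ndarray | None = None
    trough_values: np.ndarray | None = None


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def detect_peaks(
    signal: np.ndarray,
    dt: float,
    window: int = 21,
    prominence_frac: float = 0.1,
    component: int = 0,
) -> PeakTable:
    """Local maxima of the moving-average-smoothed signal.

    ``signal`` may be a 1-D series or an (n_steps, 2) trajectory, in which
    case ``component`` selects the coordinate. Peaks must exceed a prominence
    of ``prominence_frac`` times the signal range. Fewer than two peaks
    yields an empty table (degenerate/constant signals).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(signal, float)
    if x.ndim == 2:
        x = x[:, component]
    xs = _smooth(x, window)
    rng_ = xs.max() - xs.min()
    if rng_ <= 0:
        return PeakTable(np.empty(0), window, component)
    idx, props = find_peaks(xs, prominence=prominence_frac * rng_)
    tidx, tprops = find_peaks(-xs, prominence=prominence_frac * rng_)
    if len(idx) < 2:
        return PeakTable(np.empty(0), window, component)
    return PeakTable(
        peak_times=idx * dt,
        smoothing_window=window,
        component=component,
        peak_values=xs[idx],
        trough_values=xs[tidx] if len(tidx) else None,
    )


@dataclass
class OscillationStats:
    m_i: np.ndarray               # mean i-th peak time
    var_i: np.ndarray             # variance of i-th peak time
    n_i: np.ndarray               # trajectories contributing to index i
    D_peak: float                 # slope of var_i vs m_i (time units)
    period_T: float
    D_phi: float
    amplitude_1: float | None
    amplitude_2: float | None = None
    dropped: dict = field(default_factory=dict)


def peak_time_statistics(
    tables: list[PeakTable],
    tables_second: list[PeakTable] | None = None,
    skip_frac: float = 0.1,
) -> OscillationStats:
    """Ensemble peak-time statistics and the peak-time diffusion constant.

    For trajectories started from a common initial condition, m_i and
    sigma_i^2 are the mean and variance of the i-th peak time over the
    ensemble; asymptotically sigma_i^2 grows linearly with m_i and the OLS
    slope (excluding the first ``skip_frac`` of peak indices, where the
    common start suppresses variance) is the peak-time diffusion constant.
    The period is the mean of m_i / i over the same asymptotic range.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 trajectories")
    n_peaks = min((len(t.peak_times) for t in tables if len(t.peak_times)), default=0)
    if n_peaks < 2:
        raise ValueError("fewer than 2 common peaks across the ensemble")
    dropped = {"trajectories_without_peaks": sum(1 for t in tables if len(t.peak_times) == 0)}
    mat = np.array([t.peak_times[:n_peaks] for t in tables if len(t.peak_times) >= n_peaks])
    dropped["trajectories_short"] = len(tables) - len(mat) - dropped["trajectories_without_peaks"]
    if dropped["trajectories_short"] or dropped["trajectories_without_peaks"]:
        warnings.warn(
            f"dropped {dropped} trajectories lacking the common peak count",
            stacklevel=2,
        )
    m_i = mat.mean(axis=0)
    var_i = mat.var(axis=0, ddof=1)
    i = np.arange(1, n_peaks + 1)
    lo = max(1, int(np.ceil(skip_frac * n_peaks)))
    if n_peaks - lo < 2:
        lo = max(0, n_peaks - 2)
    D_peak = float(np.polyfit(m_i[lo:], var_i[lo:], 1)[0]) if n_peaks - lo >= 2 else 0.0
    period = float(np.mean(m_i[lo:] / i[lo:]))
    amp1 = _mean_amplitude(tables)
    amp2 = _mean_amplitude(tables_second) if tables_second else None
    return OscillationStats(
        m_i=m_i, var_i=var_i, n_i=np.full(n_peaks, len(mat)),
        D_peak=D_peak, period_T=period,
        D_phi=phase_diffusion(max(D_peak, 0.0), period),
        amplitude_1=amp1, amplitude_2=amp2, dropped=dropped,
    )


def _mean_amplitude(tables: list[PeakTable] | None) -> float | None:
    if not tables:
        return None
    vals = []
    for t in tables:
        if t.peak_values is not None and t.trough_values is not None and len(t.trough_values):
            vals.append(0.5 * (t.peak_values.mean() - t.trough_values.mean()))
    return float(np.mean(vals)) if vals else None


def phase_diffusion(D_peak: float, period_T: float) -> float:
    """Phase diffusion constant D_phi = D_peak (2 pi)^2 / (2 T).

    The conversion from the peak-time diffusion constant (units of time) to
    phase units (rad^2/time) is linear in D_peak; this declared convention is
    documented so any alternative linear rescaling is recoverable from
    D_peak and T.
    """
    if period_T <= 0:
        raise ValueError("period must be positive")
    return D_peak * (2 * np.pi) ** 2 / (2 * period_T)


@dataclass
class AutocorrResult:
    lags: np.ndarray
    C: np.ndarray
    tau_c: float | None
    T_fit: float | None
    fit_rss: float | None
    tau_capped: bool = False


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased, normalized autocorrelation of a mean-removed series via FFT."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(X * np.conj(X))[: max_lag + 1]
    return acf / acf[0]


def autocorrelation_fit(
    signal: np.ndarray,
    dt: float,
    max_lag: int,
    component: int = 0,
    tau_cap_factor: float = 10.0,
) -> AutocorrResult:
    """Fit C(t) = exp(-t/tau_c) cos(2 pi t / T) to the trajectory autocorrelation.

    Initial values come from the periodogram peak; tau_c fits hitting the cap
    (``tau_cap_factor`` times the lag window) are reported as lower bounds
    with ``tau_capped=True``. A failed fit returns the raw C(t) with None
    parameters.
    """
    x = np.asarray(signal, float)
    if x.ndim == 2:
        x = x[:, component]
    C = autocorrelation(x, max_lag)
    lags = np.arange(max_lag + 1) * dt
    # initial period from the dominant frequency
    freqs = np.fft.rfftfreq(len(x), dt)
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    f0 = freqs[1 + np.argmax(power[1:])] if len(power) > 1 else 1.0 / (max_lag * dt)
    T0 = 1.0 / f0 if f0 > 0 else max_lag * dt
    return fit_autocorrelation_curve(lags, C, T_init=T0,
                                     tau_cap_factor=tau_cap_factor)


def fit_autocorrelation_curve(
    lags: np.ndarray,
    C: np.ndarray,
    T_init: float | None = None,
    tau_cap_factor: float = 10.0,
) -> AutocorrResult:
    """Fit exp(-t/tau_c) cos(2 pi t / T) to an autocorrelation curve."""
    lags = np.asarray(lags, float)
    C = np.asarray(C, float)
    dt = lags[1] - lags[0]
    span = lags[-1]
    cap = tau_cap_factor * span
    if T_init is None:
        # first zero crossing approximates a quarter period
        below = np.nonzero(C < 0)[0]
        T_init = 4 * lags[below[0]] if len(below) else span

    def model(t, tau, T):
        return np.exp(-t / tau) * np.cos(2 * np.pi * t / T)

    try:
        popt, _ = curve_fit(
            model, lags, C, p0=[span / 3, T_init],
            bounds=([dt, 2 * dt], [cap, span * 4]),
            maxfev=5000,
        )
        tau_c, T_fit = float(popt[0]), float(popt[1])
        rss = float(((C - model(lags, *popt)) ** 2).sum())
        return AutocorrResult(lags, C, tau_c, T_fit, rss,
                              tau_capped=tau_c >= 0.99 * cap)
    except RuntimeError:
        warnings.warn("autocorrelation fit did not converge", stacklevel=2)
        return AutocorrResult(lags, C, None, None, None)


@dataclass
class SpectrumResult:
    """One-sided power spectral density over angular frequency omega.

    Normalized so that the integral of S d(omega) equals the signal variance
    (window-corrected Welch estimate).
    """

    omega: np.ndarray
    S: np.ndarray
    peak_height: float
    peak_frequency: float
    peak_fwhm: float | None


def power_spectrum(
    signal: np.ndarray,
    dt: float,
    window_len: int = 4096,
    component: int = 0,
    window: str = "hann",
) -> SpectrumResult:
    """Segment-averaged (Welch) periodogram of the mean-removed signal.

    With ``window='boxcar'`` and ``window_len=len(signal)`` this reduces to
    the plain periodogram, the exact Fourier pair of the biased
    autocorrelation.
    """
    x = np.asarray(signal, float)
    if x.ndim == 2:
        x = x[:, component]
    if window_len > len(x):
        raise ValueError("window longer than the signal")
    f, Pxx = welch(x - x.mean(), fs=1.0 / dt, nperseg=window_len,
                   window=window, detrend=False)
    omega = 2 * np.pi * f
    S = Pxx / (2 * np.pi)
    k = 1 + int(np.argmax(S[1:]))
    peak_h = float(S[k])
    peak_w = float(omega[k])
    half = peak_h / 2
    above = S >= half
    lo = k
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = k
    while hi < len(S) - 1 and above[hi + 1]:
        hi += 1
    fwhm = float(omega[hi] - omega[lo]) if hi > lo else None
    return SpectrumResult(omega=omega, S=S, peak_height=peak_h,
                          peak_frequency=peak_w, peak_fwhm=fwhm)


def average_power_spectrum(
    trajs: np.ndarray,
    dt: float,
    window_len: int = 4096,
    component: int = 0,
    window: str = "hann",
) -> SpectrumResult:
    """Ensemble-averaged Welch spectrum with peak/FWHM from the mean curve.

    Averaging over trajectories smooths the periodogram enough for a stable
    full-width-at-half-maximum estimate of the oscillation line."""
    Ss = []
    for tr in trajs:
        sp = power_spectrum(tr, dt, window_len=window_len,
                            component=component, window=window)
        Ss.append(sp.S)
    S = np.mean(Ss, axis=0)
    omega = sp.omega
    k = 1 + int(np.argmax(S[1:]))
    half = S[k] / 2
    above = S >= half
    lo = k
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = k
    while hi < len(S) - 1 and above[hi + 1]:
        hi += 1
    return SpectrumResult(omega=omega, S=S, peak_height=float(S[k]),
                          peak_frequency=float(omega[k]),
                          peak_fwhm=float(omega[hi] - omega[lo]) if hi > lo else None)


def ensemble_autocorrelation_fit(
    trajs: np.ndarray,
    dt: float,
    max_lag: int,
    component: int = 0,
) -> AutocorrResult:
    """Fit the coherence-time model to the ensemble-mean autocorrelation."""
    Cs = []
    for tr in trajs:
        x = np.asarray(tr, float)
        if x.ndim == 2:
            x = x[:, component]
        Cs.append(autocorrelation(x, max_lag))
    C = np.mean(Cs, axis=0)
    lags = np.arange(max_lag + 1) * dt
    return fit_autocorrelation_curve(lags, C)


@dataclass
class CoherenceResult:
    xi: float
    lag_tau: float
    center: np.ndarray
    n_steps_used: int
    n_excluded: int = 0


def phase_coherence(
    traj: np.ndarray,
    dt: float,
    lag_tau: float,
    center,
) -> CoherenceResult:
    """Phase coherence xi = 2 sum theta(phi) |phi| / sum |phi| - 1.

    phi(t) is the signed angle (counterclockwise positive) from N(t) to
    N(t + tau) where N = state - center; theta(phi) = 1 for phi > 0 else 0.
    xi = +1 for a deterministic counterclockwise cycle, -1 for its time
    reversal, ~0 for isotropic diffusion. Steps where N vanishes are
    excluded and counted.
    """
    traj = np.asarray(traj, float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must be (n_steps, 2)")
    k = int(round(lag_tau / dt))
    if k < 1 or k >= len(traj):
        raise ValueError("lag_tau must be positive and shorter than the trajectory")
    N = traj - np.asarray(center, float)
    a, b = N[:-k], N[k:]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    valid = (na > 0) & (nb > 0)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(1)
    phi = np.arctan2(cross[valid], dot[valid])
    denom = np.abs(phi).sum()
    if denom == 0:
        xi = 0.0
    else:
        xi = float(2 * (np.abs(phi)[phi > 0]).sum() / denom - 1)
    return CoherenceResult(
        xi=xi, lag_tau=k * dt, center=np.asarray(center, float),
        n_steps_used=int(valid.sum()), n_excluded=int((~valid).sum()),
    )
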