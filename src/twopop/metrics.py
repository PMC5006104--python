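"""Input-output response metrics for model traces and LFP/MUA-like signals.

Implements the analysis battery used throughout: trial-by-trial (TbT)
reliability as the mean pairwise correlation of single-trial responses;
stimulus-response cross-correlation peak (I-O amp) and decay constant
(I-O tau, exponential fit of the trial-averaged correlogram from its peak to
the 100 ms lag); time to half-maximal cumulative response (T50; 0-100 ms
window for model traces, 10-80 ms for spike trains, the latter offset
accounting for sensory conduction delay); multitaper band power; evoked
response amplitude; LFP preprocessing (zero-phase 100 Hz low-pass, 200 Hz
resampling); and the paired t test used for control-vs-modulated session
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from scipy.optimize import curve_fit

__all__ = [
    "ResponseSet", "SpikeSet", "IOMetrics", "UndefinedMetricError",
    "tbt_reliability", "io_correlation", "io_correlogram", "t50_model",
    "t50_spikes", "band_power", "response_amplitude", "preprocess_lfp",
    "paired_comparison",
]


class UndefinedMetricError(ValueError):
    """A metric could not be computed from the given data."""


@dataclass
class ResponseSet:
    """Equal-length single-trial continuous responses plus their stimulus.

    fs : sampling rate, samples per second.
    trials : (n_trials, n_samples) array of responses (model S_mean or LFP).
    stimulus_waveform : input reference trace on the same grid.
    event_times : stimulus onset times in ms.
    """
    fs: float
    trials: np.ndarray
    stimulus_waveform: np.ndarray
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        self.stimulus_waveform = np.asarray(self.stimulus_waveform, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.stimulus_waveform.shape[0] != self.trials.shape[1]:
            raise ValueError("stimulus waveform must share the trial grid")


@dataclass
class SpikeSet:
    """Per-trial spike-time lists (ms) with stimulus onsets (ms)."""
    trials: list
    event_times: np.ndarray

    def __post_init__(self):
        self.trials = [np.sort(np.asarray(t, dtype=float)) for t in self.trials]
        self.event_times = np.asarray(self.event_times, dtype=float)


@dataclass
class IOMetrics:
    """Bundle of the standard input-output metrics for one condition."""
    tbt_r: float = np.nan
    io_amp: float = np.nan
    io_tau: float = np.nan  # ms
    t50: float = np.nan     # ms
    resp_amp: float = np.nan
    power_2hz: float = np.nan


def tbt_reliability(rs: ResponseSet) -> float:
    """Mean Pearson correlation over all unordered trial pairs at zero lag.

    Constant (zero-variance) trials are excluded with a warning; if fewer
    than two variable trials remain the metric is undefined.
    """
    X = rs.trials
    if X.shape[0] < 2:
        raise UndefinedMetricError("tbt_reliability needs >= 2 trials")
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"tbt_reliability: excluding {int((~keep).sum())} "
                      "constant trial(s)", stacklevel=2)
    if keep.sum() < 2:
        raise UndefinedMetricError("all trial pairs degenerate")
    C = np.corrcoef(X[keep])
    iu = np.triu_indices_from(C, k=1)
    return float(C[iu].mean())


def io_correlogram(rs: ResponseSet, max_lag: float = 100.0) -> np.ndarray:
    """Per-trial normalized stimulus-response cross-correlation.

    Pearson correlation between the stimulus waveform and each trial at
    response lags 0..max_lag ms (response lagging the stimulus).  Returns an
    (n_trials, n_lags) array.
    """
    s = rs.stimulus_waveform
    if s.std() == 0:
        raise UndefinedMetricError("stimulus waveform is constant")
    X = rs.trials
    n = X.shape[1]
    L = int(round(max_lag * rs.fs / 1000.0))
    if L >= n:
        raise UndefinedMetricError("trials shorter than the lag window")
    out = np.empty((X.shape[0], L + 1))
    for lag in range(L + 1):
        a = s[: n - lag]
        B = X[:, lag:n]
        a0 = a - a.mean()
        B0 = B - B.mean(axis=1, keepdims=True)
        denom = np.sqrt((a0 @ a0) * (B0 * B0).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, lag] = np.where(denom > 0, (B0 @ a0) / denom, 0.0)
    return out


def io_correlation(rs: ResponseSet, max_lag: float = 100.0):
    """(io_amp, io_tau): cross-correlation peak and decay time constant.

    io_amp is the mean over trials of each trial's peak correlation within
    the lag window.  io_tau (ms) is the decay constant of a single
    exponential A*exp(-(lag - lag_peak)/tau) least-squares fitted to the
    trial-averaged correlogram from its peak to the max_lag lag; a log-linear
    fit is the fallback when the tail is all-positive and the nonlinear fit
    fails.  Non-positive or failed fits raise :class:`UndefinedMetricError`.
    """
    cg = io_correlogram(rs, max_lag)
    io_amp = float(cg.max(axis=1).mean())
    avg = cg.mean(axis=0)
    lag_ms = np.arange(avg.shape[0]) * 1000.0 / rs.fs
    p = int(np.argmax(avg))
    y = avg[p:]
    x = lag_ms[p:] - lag_ms[p]
    if y.shape[0] < 3:
        raise UndefinedMetricError("correlogram peak too close to the lag "
                                   "window edge for an exponential fit")
    tau = None
    try:
        popt, _ = curve_fit(lambda t, A, tau: A * np.exp(-t / tau), x, y,
                            p0=(y[0], 20.0), maxfev=5000,
                            bounds=([-np.inf, 1e-3], [np.inf, np.inf]))
        tau = float(popt[1])
    except (RuntimeError, TypeError):
        if np.all(y > 0):  # log-linear fallback
            slope, intercept = np.polyfit(x, np.log(y), 1)
            tau = -1.0 / slope if slope < 0 else -1.0
    if tau is None or not np.isfinite(tau) or tau <= 0:
        raise UndefinedMetricError(
            f"exponential fit of the cross-correlogram failed (tau={tau!r}, "
            f"peak lag {lag_ms[p]:.1f} ms, peak {avg[p]:.3f})")
    return io_amp, tau


def _event_indices(rs: ResponseSet, baseline_ms: float, post_ms: float):
    n = rs.trials.shape[1]
    bl = int(round(baseline_ms * rs.fs / 1000.0))
    post = int(round(post_ms * rs.fs / 1000.0))
    idx = []
    for t_ev in rs.event_times:
        i = int(round(t_ev * rs.fs / 1000.0))
        if i - bl < 0 or i + post > n:
            continue
        idx.append(i)
    if not idx:
        raise UndefinedMetricError("no events with a full analysis window")
    return idx, bl, post


def t50_model(rs: ResponseSet, window=(0.0, 100.0), baseline_ms: float = 50.0,
              drawdown_tol: float = 0.25) -> float:
    """Time to half-maximal cumulative response for continuous traces (ms).

    Event-aligned responses (baseline = mean of the 50 ms pre-event window)
    are averaged across all events and trials; the cumulative profile over
    ``window`` post-stimulus is normalized and the 0.5 crossing is located by
    linear interpolation.  A net-negative or materially non-monotone
    cumulative profile (drawdown beyond ``drawdown_tol`` of its final value)
    makes the metric undefined.
    """
    if rs.event_times.size < 1:
        raise UndefinedMetricError("t50_model needs at least one event")
    idx, bl, post = _event_indices(rs, baseline_ms, window[1])
    w0 = int(round(window[0] * rs.fs / 1000.0))
    segs = []
    for i in idx:
        base = rs.trials[:, i - bl:i].mean(axis=1, keepdims=True)
        segs.append(rs.trials[:, i + w0:i + post] - base)
    profile = np.concatenate(segs, axis=0).mean(axis=0)
    cum = np.cumsum(profile)
    if cum[-1] <= 0:
        raise UndefinedMetricError("cumulative response profile is not positive")
    c = cum / cum[-1]
    drawdown = float(np.max(np.maximum.accumulate(c) - c))
    if drawdown > drawdown_tol:
        raise UndefinedMetricError(
            f"cumulative profile non-monotone (drawdown {drawdown:.2f})")
    step = 1000.0 / rs.fs
    j = int(np.argmax(c >= 0.5))
    prev = c[j - 1] if j > 0 else 0.0
    frac = (0.5 - prev) / (c[j] - prev)
    # c[j] accounts for response mass up to the right edge of sample j
    return window[0] + (j + frac) * step


def t50_spikes(ss: SpikeSet, window=(10.0, 80.0)) -> float:
    """Time to half-maximal cumulative spiking across events (ms).

    Spike times are pooled relative to every stimulus onset, restricted to
    the analysis window (10-80 ms by default, the lower edge absorbing the
    sensory conduction delay), and the interpolated 0.5 point of the
    normalized cumulative count — the median pooled latency — is returned.
    """
    rel = []
    for spikes in ss.trials:
        for t_ev in ss.event_times:
            d = spikes - t_ev
            rel.append(d[(d >= window[0]) & (d <= window[1])])
    pooled = np.concatenate(rel) if rel else np.array([])
    if pooled.size == 0:
        raise UndefinedMetricError("no spikes within the analysis window")
    return float(np.median(pooled))


def band_power(trace, fs: float, freq: float = 2.0, nw: float = 4.0,
               n_tapers: int | None = None, method: str = "multitaper") -> float:
    """PSD estimate at the frequency bin containing ``freq``.

    Default is a multitaper estimate (DPSS tapers, time-bandwidth product 4,
    2*nw-1 tapers); ``method="periodogram"`` uses a Hann-windowed
    periodogram, appropriate for short model traces.  The trace mean is
    removed first.  Power scales with squared amplitude for a sinusoid.
    """
    x = np.asarray(trace, dtype=float)
    n = x.shape[0]
    if n < 2 * fs / freq:
        raise ValueError("trace shorter than two cycles of the target frequency")
    x = x - x.mean()
    if method == "periodogram":
        f, p = signal.periodogram(x, fs=fs, window="hann")
    elif method == "multitaper":
        K = n_tapers if n_tapers is not None else int(2 * nw - 1)
        tapers = signal.windows.dpss(n, nw, K)
        F = np.fft.rfft(tapers * x[None, :], axis=1)
        p = (2.0 / fs) * (np.abs(F) ** 2).mean(axis=0)
        p[0] /= 2.0
        if n % 2 == 0:
            p[-1] /= 2.0
        f = np.fft.rfftfreq(n, 1.0 / fs)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return float(p[np.argmin(np.abs(f - freq))])


def response_amplitude(rs: ResponseSet, window_ms: float | None = None,
                       baseline_ms: float = 50.0) -> float:
    """Mean baseline-subtracted peak response over all events and trials.

    The peak is taken within [onset, onset + window_ms]; when ``window_ms``
    is None the window runs to the next event onset (or trace end).
    """
    if rs.event_times.size < 1:
        raise UndefinedMetricError("response_amplitude needs at least one event")
    n = rs.trials.shape[1]
    bl = int(round(baseline_ms * rs.fs / 1000.0))
    onsets = np.sort(rs.event_times)
    peaks = []
    for k, t_ev in enumerate(onsets):
        i = int(round(t_ev * rs.fs / 1000.0))
        if window_ms is None:
            j = (int(round(onsets[k + 1] * rs.fs / 1000.0))
                 if k + 1 < onsets.size else n)
        else:
            j = i + int(round(window_ms * rs.fs / 1000.0))
        if i - bl < 0 or j > n or j <= i:
            continue
        base = rs.trials[:, max(i - bl, 0):i].mean(axis=1)
        peaks.append((rs.trials[:, i:j].max(axis=1) - base))
    if not peaks:
        raise UndefinedMetricError("no events with a full response window")
    return float(np.concatenate(peaks).mean())


def preprocess_lfp(raw, fs_in: float, cutoff: float = 100.0,
                   fs_out: float = 200.0):
    """Zero-phase 100 Hz low-pass then resampling to 200 samples/s.

    Fourth-order Butterworth applied forward-backward (sosfiltfilt), then
    stride decimation when fs_in is an integer multiple of fs_out and
    polyphase resampling otherwise.  Requires fs_in >= 4*cutoff so the
    cutoff is honored.
    """
    if fs_in < 4 * cutoff:
        raise ValueError(f"fs_in must be >= {4 * cutoff} to low-pass at {cutoff} Hz")
    x = np.asarray(raw, dtype=float)
    sos = signal.butter(4, cutoff, fs=fs_in, output="sos")
    y = signal.sosfiltfilt(sos, x)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        return y[:: int(round(ratio))]
    from fractions import Fraction
    fr = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return signal.resample_poly(y, fr.numerator, fr.denominator)


def paired_comparison(control, modulated):
    """Two-tailed paired Student's t test: (t, p, df) with df = n - 1.

    Identical samples give (0, 1, n-1) by convention; a nonzero constant
    difference (zero variance but nonzero mean) is an error because t is
    unbounded.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(modulated, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = b - a
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 1.0, a.size - 1
        raise UndefinedMetricError("zero variance of paired differences")
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue), a.size - 1
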