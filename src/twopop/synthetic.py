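"""Surrogate LFP/MUA sessions with controllable ground truth.

These sessions emulate the statistical structure of anesthetized-cortex
recordings used in sensory-modulation experiments: an LFP-like continuous
trace containing a band-limited 1-4 Hz slow oscillation, stimulus-evoked
negative transients and white measurement noise, and an MUA-like spike train
with a baseline rate plus an event-locked rate kernel that starts 10 ms
after each stimulus (a sensory conduction delay).  The "modulated" condition
mimics the feedback-activated state — reduced slow-oscillation power and a
faster evoked kernel — so the full metrics and paired-comparison workflow
can be exercised offline with known-direction effects.  Only directions and
structure are emulated, not in vivo magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .metrics import ResponseSet, SpikeSet

__all__ = ["SessionSpec", "SyntheticSession", "gen_lfp_session",
           "gen_spike_session", "session_pair", "lfp_response_set",
           "spike_set", "stimulus_reference"]

#: stimulus amplitude levels; deflection velocities of 140-1400 deg/s
#: mapped linearly to gain multipliers 0.1-1.0
AMP_LEVELS = tuple(np.round(np.linspace(0.1, 1.0, 10), 3))


@dataclass(frozen=True)
class SessionSpec:
    """Ground-truth generative parameters of one surrogate session.

    slow_osc_power : SD (a.u.) of the band-limited 1-4 Hz component.
    evoked_kernel_tau : decay of the evoked LFP kernel / spike-rate kernel, ms.
    evoked_gain : scales the evoked LFP deflection (a.u. per unit amplitude).
    noise_sd : white measurement noise SD (a.u.).
    baseline_rate / evoked_rate_gain : MUA firing-rate parameters (Hz).
    conduction_delay : latency between stimulus and the rate kernel, ms.
    Events are a fixed schedule of 5 ms ramp stimuli with amplitudes cycling
    through :data:`AMP_LEVELS`, identical across trials.
    """
    condition: str = "control"
    slow_osc_power: float = 1.0
    evoked_kernel_tau: float = 25.0
    evoked_gain: float = 1.0
    trial_count: int = 20
    trial_duration: float = 3000.0  # ms
    fs: float = 1000.0
    noise_sd: float = 0.1
    baseline_rate: float = 5.0
    evoked_rate_gain: float = 80.0
    conduction_delay: float = 10.0
    evoked_profile: str = "alpha"   # "alpha" | "delta"
    # fixed but irregular schedule: commensurate spacing would phase-lock
    # the 1-4 Hz slow oscillation to the events and bias aligned averages
    event_onsets: tuple = (300.0, 620.0, 905.0, 1260.0, 1515.0, 1880.0,
                           2140.0, 2475.0, 2730.0)
    event_amplitudes: tuple = tuple(AMP_LEVELS[k % 10] for k in range(9))
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("control", "modulated"):
            raise ValueError("condition must be 'control' or 'modulated'")
        for name in ("slow_osc_power", "evoked_gain", "noise_sd",
                     "baseline_rate", "evoked_rate_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.evoked_profile not in ("alpha", "delta"):
            raise ValueError("evoked_profile must be 'alpha' or 'delta'")
        if len(self.event_onsets) != len(self.event_amplitudes):
            raise ValueError("one amplitude per event onset required")

    @classmethod
    def control(cls, seed: int = 0, **over) -> "SessionSpec":
        return cls(condition="control", seed=seed, **over)

    @classmethod
    def modulated(cls, seed: int = 0, **over) -> "SessionSpec":
        """Feedback-modulated condition: halved slow-oscillation power and a
        faster evoked kernel (25 -> 15 ms)."""
        over.setdefault("slow_osc_power", 0.5)
        over.setdefault("evoked_kernel_tau", 15.0)
        return cls(condition="modulated", seed=seed, **over)


@dataclass
class SyntheticSession:
    """Generated session: LFP trials and/or spike trains plus ground truth."""
    truth: SessionSpec
    fs: float
    events: np.ndarray            # onsets, ms
    amplitudes: np.ndarray
    lfp: np.ndarray | None = None     # (n_trials, n_samples)
    spikes: list | None = None        # per-trial spike-time arrays, ms


def session_pair(seed: int = 0, control_over: dict | None = None,
                 modulated_over: dict | None = None):
    """Matched (control, modulated) specs sharing a seed.

    The two conditions must differ in at least one ground-truth field —
    otherwise the pair carries no recoverable effect.
    """
    c = SessionSpec.control(seed=seed, **(control_over or {}))
    m = SessionSpec.modulated(seed=seed, **(modulated_over or {}))
    diff = [f.name for f in fields(SessionSpec)
            if f.name not in ("condition", "seed")
            and getattr(c, f.name) != getattr(m, f.name)]
    if not diff:
        raise ValueError("modulated spec does not differ from control in any "
                         "ground-truth field")
    return c, m


def _slow_oscillation(rng: np.random.Generator, n: int, fs: float,
                      power: float) -> np.ndarray:
    """Band-limited random-phase 1-4 Hz process with SD ``power``."""
    white = rng.standard_normal(n)
    F = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    F[(f < 1.0) | (f > 4.0)] = 0.0
    x = np.fft.irfft(F, n)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x * (power / sd)


def _lfp_kernel(tau: float, fs: float) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized, negative-deflecting
    per the cortical LFP sign convention."""
    tau_r = tau / 4.0
    t = np.arange(0.0, 8.0 * tau, 1000.0 / fs)
    k = np.exp(-t / tau) - np.exp(-t / tau_r)
    return -k / k.max()


def gen_lfp_session(spec: SessionSpec) -> SyntheticSession:
    """LFP-like trials: slow oscillation + evoked kernels + white noise.

    Deterministic for a given (spec, seed); the random draws do not depend
    on the gain/power values, so component amplitudes can be varied without
    changing the underlying noise realization.
    """
    n = int(round(spec.trial_duration * spec.fs / 1000.0))
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 101)))
    kernel = _lfp_kernel(spec.evoked_kernel_tau, spec.fs)
    evoked = np.zeros(n)
    for onset, amp in zip(spec.event_onsets, spec.event_amplitudes):
        i = int(round(onset * spec.fs / 1000.0))
        j = min(n, i + kernel.shape[0])
        evoked[i:j] += spec.evoked_gain * amp * kernel[: j - i]
    trials = np.empty((spec.trial_count, n))
    for q in range(spec.trial_count):
        slow = _slow_oscillation(rng, n, spec.fs, spec.slow_osc_power)
        noise = rng.standard_normal(n) * spec.noise_sd
        trials[q] = slow + evoked + noise
    return SyntheticSession(truth=spec, fs=spec.fs,
                            events=np.asarray(spec.event_onsets),
                            amplitudes=np.asarray(spec.event_amplitudes),
                            lfp=trials)


def _rate_profile(spec: SessionSpec, n: int) -> np.ndarray:
    """Trial firing-rate profile (Hz) on the fs grid."""
    dt_ms = 1000.0 / spec.fs
    rate = np.full(n, spec.baseline_rate)
    tau = spec.evoked_kernel_tau
    t = np.arange(0.0, 8.0 * tau, dt_ms)
    alpha = (t / tau) * np.exp(1.0 - t / tau)  # peak 1 at t = tau
    for onset, amp in zip(spec.event_onsets, spec.event_amplitudes):
        i = int(round((onset + spec.conduction_delay) * spec.fs / 1000.0))
        if spec.evoked_profile == "delta":
            # all evoked mass concentrated tau ms after the delayed onset
            j = int(round((onset + spec.conduction_delay + tau)
                          * spec.fs / 1000.0))
            if j < n:
                rate[j] += spec.evoked_rate_gain * amp * tau / dt_ms
        else:
            j = min(n, i + alpha.shape[0])
            if j > i:
                rate[i:j] += spec.evoked_rate_gain * amp * alpha[: j - i]
    return rate


def gen_spike_session(spec: SessionSpec) -> SyntheticSession:
    """MUA-like trials: inhomogeneous Poisson spikes from the rate profile."""
    n = int(round(spec.trial_duration * spec.fs / 1000.0))
    dt_ms = 1000.0 / spec.fs
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 202)))
    rate = _rate_profile(spec, n)
    lam = rate * dt_ms * 1e-3  # expected count per bin
    edges = np.arange(n) * dt_ms
    spikes = []
    for _ in range(spec.trial_count):
        counts = rng.poisson(lam)
        total = int(counts.sum())
        times = np.repeat(edges, counts) + rng.random(total) * dt_ms
        spikes.append(np.sort(times))
    return SyntheticSession(truth=spec, fs=spec.fs,
                            events=np.asarray(spec.event_onsets),
                            amplitudes=np.asarray(spec.event_amplitudes),
                            spikes=spikes)


def stimulus_reference(spec: SessionSpec) -> np.ndarray:
    """Input reference waveform: 5 ms amplitude-scaled ramps at each onset."""
    n = int(round(spec.trial_duration * spec.fs / 1000.0))
    w = np.zeros(n)
    ramp_n = max(1, int(round(5.0 * spec.fs / 1000.0)))
    ramp = np.linspace(0.0, 1.0, ramp_n + 1)[1:]
    for onset, amp in zip(spec.event_onsets, spec.event_amplitudes):
        i = int(round(onset * spec.fs / 1000.0))
        j = min(n, i + ramp_n)
        w[i:j] += amp * ramp[: j - i]
    return w


def lfp_response_set(session: SyntheticSession,
                     invert: bool = True) -> ResponseSet:
    """ResponseSet for metric analysis of an LFP session.

    The LFP is sign-inverted by default so that evoked deflections correlate
    positively with the stimulus reference (correlational metrics are
    otherwise sign-ambiguous for negative-deflecting signals).
    """
    if session.lfp is None:
        raise ValueError("session has no LFP component")
    X = -session.lfp if invert else session.lfp
    return ResponseSet(fs=session.fs, trials=X,
                       stimulus_waveform=stimulus_reference(session.truth),
                       event_times=session.events)


def spike_set(session: SyntheticSession) -> SpikeSet:
    if session.spikes is None:
        raise ValueError("session has no spike component")
    return SpikeSet(trials=session.spikes, event_times=session.events)
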