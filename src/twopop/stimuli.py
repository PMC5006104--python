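"""External input waveforms: transient pulse trains and slow sinusoids.

Transient stimuli are 10 ms rectangular current pulses smoothed by a
first-order low-pass filter with a 10 ms time constant (mimicking synaptic
filtering of a brief sensory volley).  The slow-oscillation surrogate is a
2 Hz sinusoid applied identically to both ensembles, whose phase is drawn
fresh on each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "StimulusProgram", "pulse_train", "filter_waveform", "sinusoid",
    "coincident_series", "proportional_series",
]


def pulse_train(events, width: float = 10.0, dt: float = 0.1,
                duration: float = 1000.0):
    """Rectangular paired pulse trains from (onset_ms, amp1_nA, amp2_nA) events.

    Pulses occupy [onset, onset + width) and must not overlap.  Returns the
    two raw (unfiltered) waveforms.
    """
    n = int(round(duration / dt))
    w1 = np.zeros(n)
    w2 = np.zeros(n)
    evs = sorted(events, key=lambda e: e[0])
    for k, (onset, a1, a2) in enumerate(evs):
        if onset < 0 or onset + width > duration:
            raise ValueError(f"pulse at {onset} ms falls outside [0, {duration}] ms")
        if k + 1 < len(evs) and onset + width > evs[k + 1][0]:
            raise ValueError(f"pulses at {onset} and {evs[k+1][0]} ms overlap")
        i0 = int(round(onset / dt))
        i1 = int(round((onset + width) / dt))
        w1[i0:i1] = a1
        w2[i0:i1] = a2
    return w1, w2


def filter_waveform(raw, tau: float = 10.0, dt: float = 0.1):
    """First-order low-pass (exponential smoothing) with unit DC gain.

    Discretized exactly: y[k] = (1-beta)*x[k] + beta*y[k-1], beta = exp(-dt/tau),
    so a unit step converges to 1 with the closed-form 1 - exp(-t/tau) profile
    (to within one sample).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    beta = np.exp(-dt / tau)
    return lfilter([1.0 - beta], [1.0, -beta], np.asarray(raw, dtype=float))


def sinusoid(freq: float = 2.0, amp: float = 0.05, phase: float = 0.0,
             dt: float = 0.1, duration: float = 1000.0):
    """amp*sin(2*pi*freq*t + phase) on the dt grid (t in ms, freq in Hz)."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    t = np.arange(int(round(duration / dt))) * dt
    return amp * np.sin(2.0 * np.pi * freq * t * 1e-3 + phase)


@dataclass
class StimulusProgram:
    """Paired external-input waveforms plus the event metadata they derive from.

    The full waveform of each ensemble is the low-pass-filtered pulse train
    plus the optional common sinusoid; everything is reconstructible (and is
    lazily rebuilt) from ``events``, the filter constants and the sine
    parameters, so serialization keeps only those.
    """
    dt: float
    duration: float
    events: tuple  # ((onset_ms, amp1_nA, amp2_nA), ...)
    pulse_width: float = 10.0
    filter_tau: float = 10.0
    sine_amp: float = 0.0
    sine_freq: float = 2.0
    sine_phase: float = 0.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e[0] for e in self.events])

    @cached_property
    def _transients(self):
        r1, r2 = pulse_train(self.events, self.pulse_width, self.dt,
                             self.duration)
        return (filter_waveform(r1, self.filter_tau, self.dt),
                filter_waveform(r2, self.filter_tau, self.dt))

    @property
    def transient1(self) -> np.ndarray:
        return self._transients[0]

    @property
    def transient2(self) -> np.ndarray:
        return self._transients[1]

    @cached_property
    def _sine(self):
        if self.sine_amp == 0.0:
            return np.zeros(self.n_samples)
        return sinusoid(self.sine_freq, self.sine_amp, self.sine_phase,
                        self.dt, self.duration)

    @property
    def waveform1(self) -> np.ndarray:
        return self.transient1 + self._sine

    @property
    def waveform2(self) -> np.ndarray:
        return self.transient2 + self._sine

    def with_phase(self, phase: float) -> "StimulusProgram":
        return replace(self, sine_phase=float(phase))

    def to_dict(self) -> dict:
        return {
            "dt": self.dt, "duration": self.duration,
            "events": [list(e) for e in self.events],
            "pulse_width": self.pulse_width, "filter_tau": self.filter_tau,
            "sine_amp": self.sine_amp, "sine_freq": self.sine_freq,
            "sine_phase": self.sine_phase,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProgram":
        d = dict(d)
        d["events"] = tuple(tuple(e) for e in d["events"])
        return cls(**d)


def coincident_series(I1_amp: float = 0.5, ratios=None, isi: float = 1000.0,
                      dt: float = 0.1, width: float = 10.0,
                      first_onset: float = 500.0, sine_amp: float = 0.0,
                      sine_freq: float = 2.0, sine_phase: float = 0.0,
                      ) -> StimulusProgram:
    """Series of simultaneous pulse pairs with increasing competitor amplitude.

    Ensemble 1 receives a fixed-amplitude pulse on every stimulus; ensemble 2
    receives ratio * I1_amp, with the ratio grid running from 0 to 4 (13
    linearly spaced values by default, which puts the I1 = I2 condition at
    stimulus number 4, counting from 1).
    """
    if ratios is None:
        ratios = np.linspace(0.0, 4.0, 13)
    ratios = np.asarray(ratios, dtype=float)
    if np.any(np.diff(ratios) < 0):
        raise ValueError("ratios must be nondecreasing")
    if ratios[0] != 0.0 or ratios[-1] != 4.0:
        raise ValueError("ratio grid must start at 0 and end at 4")
    events = tuple((first_onset + k * isi, I1_amp, r * I1_amp)
                   for k, r in enumerate(ratios))
    duration = first_onset + len(ratios) * isi
    return StimulusProgram(dt=dt, duration=duration, events=events,
                           pulse_width=width, sine_amp=sine_amp,
                           sine_freq=sine_freq, sine_phase=sine_phase)


def proportional_series(amps=None, ratio: float = 0.6, isi: float = 400.0,
                        dt: float = 0.1, width: float = 10.0,
                        first_onset: float = 200.0, sine_amp: float = 0.0,
                        sine_freq: float = 2.0, sine_phase: float = 0.0,
                        ) -> StimulusProgram:
    """Sensory-like series: pulse pairs of fixed proportion Istim2 = ratio*Istim1.

    Default amplitudes are 10 values linearly spaced over 0.06-0.6 nA,
    presented in ascending order.
    """
    if amps is None:
        amps = np.linspace(0.06, 0.6, 10)
    amps = np.asarray(amps, dtype=float)
    if np.any(amps < 0.06 - 1e-12) or np.any(amps > 0.6 + 1e-12):
        raise ValueError("transient amplitudes must lie within [0.06, 0.6] nA")
    events = tuple((first_onset + k * isi, a, ratio * a)
                   for k, a in enumerate(amps))
    duration = first_onset + len(amps) * isi
    return StimulusProgram(dt=dt, duration=duration, events=events,
                           pulse_width=width, sine_amp=sine_amp,
                           sine_freq=sine_freq, sine_phase=sine_phase)
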