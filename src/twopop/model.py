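"""Reduced two-ensemble cortical circuit model.

The model is the two-variable mean-field reduction of a spiking network with
two recurrently connected excitatory populations and shared global
inhibition.  Each ensemble is described by a single synaptic gating variable
``S`` in [0, 1], driven by a rate transfer function ``r = f(I)`` of its total
synaptic input.  Effective self-excitation ``Js`` and effective
cross-inhibition ``Jo`` (stored as the magnitude of the net inhibitory
cross-coupling) parameterize the circuit; background drive is an
Ornstein-Uhlenbeck current with mean ``Io``.

Units throughout: time in ms, currents in nA, rates in Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._engine import SINGULARITY_TOL, _integrate

__all__ = [
    "TransferParams", "Couplings", "NoiseSpec", "GatingParams", "ModelSpec",
    "TrialTrace", "IntegrationDivergedError",
    "firing_rate", "total_inputs", "step_ou_noise", "gating_derivative",
    "steady_state_gating", "integrate_trial", "integrate_trials",
]

#: Gating-bound overshoot beyond which integration is treated as broken
#: rather than silently clipped.
OVERSHOOT_TOL = 1e-6


class IntegrationDivergedError(RuntimeError):
    """Raised when the state became non-finite or left [0, 1] materially."""


@dataclass(frozen=True)
class TransferParams:
    """Constants of the input-to-rate transfer function ``f(I)``.

    a : gain, Hz per nA.
    b : threshold, Hz.
    d : curvature, s (sets the softness of rectification near threshold).
    """
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.d > 0):
            raise ValueError("transfer-function constants must be positive")


@dataclass(frozen=True)
class Couplings:
    """Effective synaptic couplings, identical for both ensembles.

    Js : net self-excitation (nA); recurrent excitation minus within-ensemble
         feedback inhibition.
    Jo : magnitude of net cross-inhibition (nA); enters inputs with a minus
         sign, so larger Jo means stronger lateral suppression.
    """
    Js: float
    Jo: float

    def __post_init__(self):
        if self.Js < 0 or self.Jo < 0:
            raise ValueError("Js and Jo must be non-negative "
                             "(Jo is stored as a magnitude)")


@dataclass(frozen=True)
class NoiseSpec:
    """Background current: OU process with mean Io, SD sigma_noise (nA)."""
    Io: float = 0.32
    sigma_noise: float = 0.02
    tau_noise: float = 10.0  # ms

    def __post_init__(self):
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.tau_noise <= 0:
            raise ValueError("tau_noise must be > 0")


@dataclass(frozen=True)
class GatingParams:
    """Gating-variable kinetics: saturation factor gamma, time constant tau_s (ms)."""
    gamma: float = 0.641
    tau_s: float = 100.0

    def __post_init__(self):
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """One circuit instance: transfer constants, couplings, noise, gating."""
    couplings: Couplings
    transfer: TransferParams = TransferParams()
    noise: NoiseSpec = NoiseSpec()
    gating: GatingParams = GatingParams()

    @classmethod
    def make(cls, Js: float, Jo: float, Io: float = 0.32,
             sigma_noise: float = 0.02, **kw) -> "ModelSpec":
        """Convenience constructor for the commonly swept parameters."""
        return cls(couplings=Couplings(Js, Jo),
                   noise=NoiseSpec(Io=Io, sigma_noise=sigma_noise), **kw)

    def with_couplings(self, Js: float, Jo: float) -> "ModelSpec":
        return replace(self, couplings=Couplings(Js, Jo))


@dataclass
class TrialTrace:
    """Recorded state of one simulated trial, sampled every ``dt`` ms."""
    dt: float
    t: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    Inoise1: np.ndarray
    Inoise2: np.ndarray
    seed: object = None

    @property
    def S_mean(self) -> np.ndarray:
        """Average population activity (S1 + S2)/2, the LFP/MUA analogue."""
        return (self.S1 + self.S2) / 2.0


def firing_rate(I, p: TransferParams = TransferParams()):
    """Transfer function r = (a*I - b) / (1 - exp(-d*(a*I - b))).

    Strictly positive and strictly increasing in I.  The removable
    singularity at a*I = b is evaluated by the two-term Taylor limit
    1/d + (a*I - b)/2.  Accepts scalars or arrays; raises on non-finite
    input.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("firing_rate: input current must be finite")
    x = p.a * I - p.b
    near = np.abs(x) < SINGULARITY_TOL
    with np.errstate(over="ignore", invalid="ignore"):
        denom = 1.0 - np.exp(-p.d * x)
        r = np.where(near, 1.0 / p.d + 0.5 * x,
                     np.divide(x, denom, out=np.zeros_like(x),
                               where=denom != 0))
    return float(r) if r.ndim == 0 else r


def total_inputs(S1, S2, c: Couplings, Istim1=0.0, Istim2=0.0,
                 Inoise1=0.0, Inoise2=0.0):
    """Total synaptic inputs (I1, I2): self-excitation minus cross-inhibition
    plus external and background currents, symmetrically for both ensembles."""
    I1 = c.Js * S1 - c.Jo * S2 + Istim1 + Inoise1
    I2 = c.Js * S2 - c.Jo * S1 + Istim2 + Inoise2
    return I1, I2


def step_ou_noise(x, spec: NoiseSpec, dt: float, z):
    """One Euler-Maruyama update of the background OU current.

    The white-noise increment is scaled as sigma*sqrt(2*dt/tau) so that the
    stationary standard deviation of the continuum process equals
    ``sigma_noise`` (the discrete chain's stationary SD is inflated by the
    factor (1 - dt/(2*tau))**-0.5, ~0.25% at dt = 0.1 ms).  With
    sigma_noise = 0 the update decays deterministically toward Io.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= spec.tau_noise:
        warnings.warn("step_ou_noise: dt >= tau_noise; the discretization "
                      "is inaccurate at this step size", stacklevel=2)
    alpha = dt / spec.tau_noise
    c = spec.sigma_noise * math.sqrt(2.0 * dt / spec.tau_noise)
    return x + alpha * (spec.Io - x) + c * z


def gating_derivative(S, r, g: GatingParams = GatingParams()):
    """dS/dt in 1/s: -S/tau_s + (1 - S)*gamma*r, with tau_s converted to s."""
    return -S / (g.tau_s * 1e-3) + (1.0 - S) * g.gamma * r


def steady_state_gating(r, g: GatingParams = GatingParams()):
    """Fixed point of the gating equation at constant rate r (Hz).

    Closed form gamma*r*tau_s / (1 + gamma*r*tau_s) with tau_s in seconds;
    lies in [0, 1).
    """
    x = g.gamma * np.asarray(r, dtype=float) * g.tau_s * 1e-3
    out = x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def _resolve_rng(seed=None, rng=None):
    if rng is not None:
        return rng
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


def integrate_trials(spec: ModelSpec, programs, rngs, duration=None,
                     dt: float = 0.1, burn_in: float = 500.0,
                     record_dt: float = 1.0, S_init=None, seeds=None):
    """Integrate a batch of trials of one circuit through the compiled kernel.

    All programs must share the same transient waveforms, grid and sinusoid
    amplitude/frequency; only the sinusoid phase may differ per trial (this
    is exactly the per-trial variation of the study protocols).  One
    ``numpy.random.Generator`` per trial supplies the noise stream.  Returns
    a list of :class:`TrialTrace`.
    """
    progs = list(programs)
    rngs = list(rngs)
    if len(progs) != len(rngs):
        raise ValueError("need one RNG per program")
    m = len(progs)
    p0 = progs[0]
    if duration is None:
        duration = p0.duration
    if abs(p0.dt - dt) > 1e-12:
        raise ValueError("program grid must match the integration step")
    n_main = int(round(duration / dt))
    if p0.n_samples < n_main:
        raise ValueError("stimulus program does not cover the trial duration")
    stride = int(round(record_dt / dt))
    if abs(stride * dt - record_dt) > 1e-9 or stride < 1:
        raise ValueError("record_dt must be an integer multiple of dt")
    trans1 = np.ascontiguousarray(p0.transient1[:n_main])
    trans2 = np.ascontiguousarray(p0.transient2[:n_main])
    phases = np.empty(m)
    for q, pr in enumerate(progs):
        if (pr.sine_amp != p0.sine_amp or pr.sine_freq != p0.sine_freq
                or pr.events != p0.events or pr.n_samples != p0.n_samples):
            raise ValueError("batched programs may differ only in sine phase")
        phases[q] = pr.sine_phase

    tr, nz, g = spec.transfer, spec.noise, spec.gating
    c = spec.couplings
    burn_steps = int(round(burn_in / dt))
    n_total = burn_steps + n_main
    n_rec = 1 + (n_main - 1) // stride

    if S_init is None:
        s0 = steady_state_gating(firing_rate(nz.Io, tr), g)
        S_init = (s0, s0)
    S = np.empty((m, 2))
    S[:, 0], S[:, 1] = S_init
    N = np.full((m, 2), nz.Io)

    if nz.sigma_noise > 0:
        z = np.empty((m, n_total, 2))
        for q, rng in enumerate(rngs):
            z[q] = rng.standard_normal((n_total, 2))
    else:
        z = np.zeros((m, 1, 2))

    Js = np.full(m, c.Js)
    Jo = np.full(m, c.Jo)
    S1o = np.empty((m, n_rec))
    S2o = np.empty((m, n_rec))
    N1o = np.empty((m, n_rec))
    N2o = np.empty((m, n_rec))
    diag = np.zeros(2)
    _integrate(S, N, Js, Jo, trans1, trans2,
               float(p0.sine_amp), float(p0.sine_freq), phases, z,
               tr.a, tr.b, tr.d, g.gamma, g.tau_s, nz.tau_noise,
               nz.Io, nz.sigma_noise, dt, burn_steps, stride,
               S1o, S2o, N1o, N2o, diag)
    if diag[1] >= 0:
        raise IntegrationDivergedError(
            f"state became non-finite at integration step {int(diag[1])}")
    if diag[0] > OVERSHOOT_TOL:
        raise IntegrationDivergedError(
            f"gating variable overshot [0, 1] by {diag[0]:.3g} "
            f"(> {OVERSHOOT_TOL}); reduce dt")
    t = np.arange(n_rec) * record_dt
    if seeds is None:
        seeds = [None] * m
    return [TrialTrace(dt=record_dt, t=t, S1=S1o[q].copy(), S2=S2o[q].copy(),
                       Inoise1=N1o[q].copy(), Inoise2=N2o[q].copy(),
                       seed=seeds[q])
            for q in range(m)]


def integrate_trial(spec: ModelSpec, program, duration=None, dt: float = 0.1,
                    seed=None, rng=None, burn_in: float = 500.0,
                    record_dt: float = 1.0, S_init=None) -> TrialTrace:
    """Integrate a single trial.

    Fixed-step explicit Euler-Maruyama integration of the coupled
    gating/noise system; identical seed and inputs give bit-identical
    output.  By default the initial gating is the closed-form fixed point at
    the background rate f(Io), and a 500 ms burn-in (noise and sinusoid
    running, transient off) precedes t = 0.
    """
    r = _resolve_rng(seed, rng)
    (trace,) = integrate_trials(spec, [program], [r], duration=duration,
                                dt=dt, burn_in=burn_in, record_dt=record_dt,
                                S_init=S_init, seeds=[seed])
    return trace
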