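"""Simulation campaigns: Js x Jo parameter sweeps and trajectory analysis.

The circuit is characterized by sweeping self-excitation (Js) and
cross-inhibition (Jo) over either the full range (Js 0.01-0.74 nA,
Jo 0.01-0.37 nA) or the transient-response range (both 0.01-0.37 nA), and by
three stimulus protocols:

* coincident series — 13 simultaneous pulse pairs, fixed 0.5 nA to ensemble
  1 and a 0-4x competitor to ensemble 2, used to map cross-suppression
  (delta-S1) and winner-take-all crossing points;
* proportional series — sensory-like pulse pairs (Istim2 = 0.6*Istim1,
  0.06-0.6 nA) with or without a 2 Hz sinusoidal background, used for the
  input-output fidelity metrics;
* sinusoid-only — 2 Hz, 0.05 nA drive, used for slow-oscillation
  propagation (2 Hz output power).

Per-cell/per-trial noise streams are keyed by (master seed, protocol tag,
Js index, Jo index, trial index), so cells are independent and results do
not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import (ResponseSet, UndefinedMetricError, band_power,
                      io_correlation, response_amplitude, t50_model,
                      tbt_reliability)
from .model import (IntegrationDivergedError, ModelSpec, TrialTrace,
                    integrate_trials)
from .stimuli import StimulusProgram, coincident_series, proportional_series

__all__ = [
    "SweepGrid", "SweepResult", "cell_seed", "run_sweep",
    "peak_trajectories", "delta_s1", "crossing_index", "classify_regime",
    "response_set_from_traces", "sensory_fidelity_cell",
    "run_fidelity_sweep", "run_coincident", "run_slow_osc", "grid_average",
]

_RANGES = {"full": ((0.01, 0.74), (0.01, 0.37)),
           "transient": ((0.01, 0.37), (0.01, 0.37))}


@dataclass(frozen=True)
class SweepGrid:
    """Sorted Js and Jo grids tagged with the range they were drawn from."""
    Js_values: tuple
    Jo_values: tuple
    range_tag: str = "transient"

    def __post_init__(self):
        if self.range_tag not in _RANGES:
            raise ValueError(f"unknown range tag {self.range_tag!r}")
        (js_lo, js_hi), (jo_lo, jo_hi) = _RANGES[self.range_tag]
        js = np.asarray(self.Js_values, dtype=float)
        jo = np.asarray(self.Jo_values, dtype=float)
        eps = 1e-9
        if np.any(np.diff(js) < 0) or np.any(np.diff(jo) < 0):
            raise ValueError("grid values must be sorted ascending")
        if js.min() < js_lo - eps or js.max() > js_hi + eps:
            raise ValueError(f"Js values outside the {self.range_tag} range")
        if jo.min() < jo_lo - eps or jo.max() > jo_hi + eps:
            raise ValueError(f"Jo values outside the {self.range_tag} range")

    @classmethod
    def transient(cls, n: int = 10) -> "SweepGrid":
        v = tuple(np.linspace(0.01, 0.37, n))
        return cls(v, v, "transient")

    @classmethod
    def full(cls, n: int = 10) -> "SweepGrid":
        return cls(tuple(np.linspace(0.01, 0.74, n)),
                   tuple(np.linspace(0.01, 0.37, n)), "full")


@dataclass
class SweepResult:
    """Per-(Js, Jo) metric table plus peak trajectories and run metadata."""
    grid: SweepGrid
    table: pd.DataFrame
    peaks: dict              # (i_js, i_jo) -> (mean S1 peaks, mean S2 peaks)
    protocol_tag: int
    master_seed: int
    traces: dict | None = None


def cell_seed(master: int, tag: int, i_js: int, i_jo: int,
              trial: int) -> np.random.SeedSequence:
    """Counter-keyed seed for one trial of one grid cell (order-free)."""
    return np.random.SeedSequence((master, tag, i_js, i_jo, trial))


def peak_trajectories(trace: TrialTrace, event_onsets):
    """Per-stimulus peak (max) of S1 and S2 in the onset-to-next-onset window."""
    onsets = np.sort(np.asarray(event_onsets, dtype=float))
    t_end = trace.t[-1] + trace.dt
    p1, p2 = [], []
    for k, t0 in enumerate(onsets):
        t1 = onsets[k + 1] if k + 1 < onsets.size else t_end
        m = (trace.t >= t0) & (trace.t < t1)
        if not m.any():
            raise ValueError(f"empty response window at onset {t0} ms")
        p1.append(trace.S1[m].max())
        p2.append(trace.S2[m].max())
    return np.array(p1), np.array(p2)


def delta_s1(peaks1) -> float:
    """Cross-suppression index: first-stimulus peak minus last-stimulus peak.

    Positive when the strongest competitor input (the last stimulus) has
    suppressed ensemble 1 relative to the competitor-free first stimulus.
    """
    peaks1 = np.asarray(peaks1, dtype=float)
    if peaks1.size < 2:
        raise ValueError("delta_s1 needs peaks from at least two stimuli")
    return float(peaks1[0] - peaks1[-1])


def crossing_index(peaks1, peaks2, tol: float = 0.01):
    """Smallest 1-based stimulus number at which S2's peak reaches S1's.

    The tolerance counts near-ties as crossings: at the equal-input stimulus
    the two trajectories intersect, and with low-amplitude noise a strict
    comparison of the sampled peaks would resolve the tie at random.
    Returns None if the trajectories never cross.
    """
    p1 = np.asarray(peaks1, dtype=float)
    p2 = np.asarray(peaks2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("peak lists must have equal length")
    hit = np.nonzero(p2 >= p1 - tol)[0]
    return int(hit[0]) + 1 if hit.size else None


def classify_regime(trace: TrialTrace, event_onsets, threshold: float = 0.3,
                    dwell_frac: float = 0.8) -> str:
    """Label a trial "sustained" or "transient".

    Sustained means that after at least one stimulus, max(S1, S2) stays
    above ``threshold`` for at least ``dwell_frac`` of the full interval to
    the next stimulus — i.e. the response outlives the inter-stimulus gap
    instead of decaying back to baseline.
    """
    onsets = np.sort(np.asarray(event_onsets, dtype=float))
    env = np.maximum(trace.S1, trace.S2)
    t_end = trace.t[-1] + trace.dt
    for k, t0 in enumerate(onsets):
        t1 = onsets[k + 1] if k + 1 < onsets.size else t_end
        m = (trace.t >= t0) & (trace.t < t1)
        if m.any() and (env[m] > threshold).mean() >= dwell_frac:
            return "sustained"
    return "transient"


def response_set_from_traces(traces: Sequence[TrialTrace],
                             program: StimulusProgram) -> ResponseSet:
    """Bundle trial S_mean traces with the transient input reference.

    The stimulus reference is the filtered transient waveform actually
    delivered to ensemble 1 (the sinusoid, when present, is background and
    not part of the input-output reference), decimated to the trace grid.
    """
    tr0 = traces[0]
    stride = int(round(tr0.dt / program.dt))
    ref = program.transient1[::stride][: tr0.t.shape[0]]
    X = np.stack([tr.S_mean for tr in traces])
    return ResponseSet(fs=1000.0 / tr0.dt, trials=X, stimulus_waveform=ref,
                       event_times=program.onsets)


def sensory_fidelity_cell(traces, program) -> dict:
    """The standard fidelity metric set for one grid cell's trials."""
    rs = response_set_from_traces(traces, program)
    out = {}
    out["tbt_r"] = tbt_reliability(rs)
    amp, tau = io_correlation(rs)
    out["io_amp"] = amp
    out["io_tau_ms"] = tau
    out["t50_ms"] = t50_model(rs)
    out["resp_amp"] = response_amplitude(rs)
    return out


def slow_osc_power_cell(traces, program) -> dict:
    """2 Hz output power of the average ensemble activity, mean over trials."""
    fs = 1000.0 / traces[0].dt
    p = [band_power(tr.S_mean, fs, freq=program.sine_freq) for tr in traces]
    return {"power_2hz": float(np.mean(p))}


def run_sweep(grid: SweepGrid, spec_template: ModelSpec,
              program_factory: Callable[[np.random.Generator], StimulusProgram],
              n_trials: int, seed: int,
              cell_fns: Sequence[Callable[[Sequence[TrialTrace], StimulusProgram],
                                          Mapping[str, float]]] = (),
              dt: float = 0.1, record_dt: float = 1.0, burn_in: float = 500.0,
              keep_traces: bool = False, protocol_tag: int = 0) -> SweepResult:
    """Run ``n_trials`` independent trials for every (Js, Jo) grid cell.

    Each trial gets a fresh generator from :func:`cell_seed`; the program
    factory may consume it (e.g. to draw the sinusoid phase) before the
    noise stream is drawn, so a 1x1 sweep is bit-identical to calling
    :func:`twopop.model.integrate_trial` with the same derived generator.
    Diverged trials are dropped and counted per cell; metric failures are
    recorded per cell and the sweep continues.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rows = []
    peaks: dict = {}
    all_traces: dict = {}
    for i, Js in enumerate(grid.Js_values):
        for j, Jo in enumerate(grid.Jo_values):
            spec = spec_template.with_couplings(Js, Jo)
            rngs = [np.random.default_rng(
                        cell_seed(seed, protocol_tag, i, j, k))
                    for k in range(n_trials)]
            programs = [program_factory(r) for r in rngs]
            row = {"Js": Js, "Jo": Jo, "i_js": i, "i_jo": j,
                   "n_failed_trials": 0, "error": ""}
            try:
                traces = integrate_trials(spec, programs, rngs, dt=dt,
                                          burn_in=burn_in,
                                          record_dt=record_dt)
            except IntegrationDivergedError:
                # retry trial-by-trial so one bad noise path does not void
                # the whole cell
                traces = []
                for pr, rg in zip(programs, rngs):
                    try:
                        traces += integrate_trials(spec, [pr], [rg], dt=dt,
                                                   burn_in=burn_in,
                                                   record_dt=record_dt)
                    except IntegrationDivergedError as exc:
                        row["n_failed_trials"] += 1
                        row["error"] = str(exc)
            if traces:
                program = programs[0]
                if program.events:
                    pk = [peak_trajectories(tr, program.onsets)
                          for tr in traces]
                    peaks[(i, j)] = (np.mean([p[0] for p in pk], axis=0),
                                     np.mean([p[1] for p in pk], axis=0))
                for fn in cell_fns:
                    try:
                        row.update(fn(traces, program))
                    except UndefinedMetricError as exc:
                        row["error"] = (row["error"] + "; " if row["error"]
                                        else "") + str(exc)
                if keep_traces:
                    all_traces[(i, j)] = traces
            else:
                row["error"] = row["error"] or "all trials diverged"
            rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(grid=grid, table=table, peaks=peaks,
                       protocol_tag=protocol_tag, master_seed=seed,
                       traces=all_traces if keep_traces else None)


def grid_average(result: SweepResult, metric: str) -> float:
    """Mean of a per-cell metric over the grid, ignoring failed cells."""
    return float(np.nanmean(result.table[metric].to_numpy()))


# ---------------------------------------------------------------------------
# Campaign front-ends

#: protocol tags entering the seed derivation
TAG_COINCIDENT = 0
TAG_FIDELITY_SINE = 1
TAG_FIDELITY_NOSINE = 2
TAG_SLOW_OSC = 3


def run_fidelity_sweep(grid: SweepGrid | None = None, with_sine: bool = True,
                       n_trials: int = 20, seed: int = 0, n_amps: int = 10,
                       isi: float = 400.0, Io: float = 0.32,
                       sigma_noise: float = 0.02, sine_amp: float = 0.05,
                       sine_freq: float = 2.0, dt: float = 0.1,
                       record_dt: float = 1.0, **kw) -> SweepResult:
    """Sensory-fidelity sweep: proportional transients +/- 2 Hz background.

    With the sinusoid present its phase is uniform-random per trial.  Noise
    parameters default to the transient-stimulus protocol values
    (Io = 0.32 nA, sigma_noise = 0.02 nA).
    """
    if grid is None:
        grid = SweepGrid.transient(10)
    amps = np.linspace(0.06, 0.6, n_amps)

    def factory(rng: np.random.Generator) -> StimulusProgram:
        if with_sine:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            return proportional_series(amps=amps, isi=isi, dt=dt,
                                       sine_amp=sine_amp,
                                       sine_freq=sine_freq, sine_phase=phase)
        return proportional_series(amps=amps, isi=isi, dt=dt, sine_amp=0.0)

    spec = ModelSpec.make(0.01, 0.01, Io=Io, sigma_noise=sigma_noise)
    tag = TAG_FIDELITY_SINE if with_sine else TAG_FIDELITY_NOSINE
    return run_sweep(grid, spec, factory, n_trials, seed,
                     cell_fns=[sensory_fidelity_cell], dt=dt,
                     record_dt=record_dt, protocol_tag=tag, **kw)


def run_coincident(Js: float, Jo: float, n_trials: int = 4, seed: int = 0,
                   I1_amp: float = 0.5, isi: float = 1000.0,
                   Io: float = 0.32, sigma_noise: float = 0.001,
                   dt: float = 0.1, record_dt: float = 1.0) -> dict:
    """Coincident-series run for one (Js, Jo) exemplar.

    Returns the trial traces, trial-averaged per-stimulus peak trajectories,
    and the derived quantities: cross-suppression index delta_s1, 1-based
    S1-S2 crossing stimulus number (None if never crossed), and the
    transient/sustained regime label (majority vote over trials).
    """
    spec = ModelSpec.make(Js, Jo, Io=Io, sigma_noise=sigma_noise)
    program = coincident_series(I1_amp=I1_amp, isi=isi, dt=dt)
    rngs = [np.random.default_rng(cell_seed(seed, TAG_COINCIDENT, 0, 0, k))
            for k in range(n_trials)]
    traces = integrate_trials(spec, [program] * n_trials, rngs, dt=dt,
                              record_dt=record_dt)
    pk = [peak_trajectories(tr, program.onsets) for tr in traces]
    p1 = np.mean([p[0] for p in pk], axis=0)
    p2 = np.mean([p[1] for p in pk], axis=0)
    labels = [classify_regime(tr, program.onsets) for tr in traces]
    regime = max(set(labels), key=labels.count)
    return {"traces": traces, "program": program, "peaks1": p1, "peaks2": p2,
            "delta_s1": delta_s1(p1), "crossing": crossing_index(p1, p2),
            "regime": regime}


def run_slow_osc(Js: float, Jo: float, Io: float = 0.32,
                 sigma_noise: float = 0.001, sine_amp: float = 0.05,
                 sine_freq: float = 2.0, duration: float = 5000.0,
                 n_trials: int = 4, seed: int = 0, dt: float = 0.1,
                 record_dt: float = 1.0) -> dict:
    """Slow-oscillation propagation run for one (Js, Jo) exemplar.

    Sinusoid-only drive with a fresh random phase per trial; returns the
    trial traces and the mean 2 Hz power of the average ensemble activity.
    """
    spec = ModelSpec.make(Js, Jo, Io=Io, sigma_noise=sigma_noise)
    base = StimulusProgram(dt=dt, duration=duration, events=(),
                           sine_amp=sine_amp, sine_freq=sine_freq)
    rngs = [np.random.default_rng(cell_seed(seed, TAG_SLOW_OSC, 0, 0, k))
            for k in range(n_trials)]
    programs = [base.with_phase(r.uniform(0.0, 2.0 * np.pi)) for r in rngs]
    traces = integrate_trials(spec, programs, rngs, dt=dt,
                              record_dt=record_dt)
    fs = 1000.0 / record_dt
    power = float(np.mean([band_power(tr.S_mean, fs, freq=sine_freq)
                           for tr in traces]))
    return {"traces": traces, "power_2hz": power}


def run_slow_osc_sweep(grid: SweepGrid | None = None, Io: float = 0.32,
                       sigma_noise: float = 0.001, sine_amp: float = 0.05,
                       sine_freq: float = 2.0, duration: float = 5000.0,
                       n_trials: int = 4, seed: int = 0, dt: float = 0.1,
                       record_dt: float = 1.0, **kw) -> SweepResult:
    """2 Hz power map over the transient-range grid (heatmap-style sweep)."""
    if grid is None:
        grid = SweepGrid.transient(10)
    base = StimulusProgram(dt=dt, duration=duration, events=(),
                           sine_amp=sine_amp, sine_freq=sine_freq)

    def factory(rng: np.random.Generator) -> StimulusProgram:
        return base.with_phase(rng.uniform(0.0, 2.0 * np.pi))

    spec = ModelSpec.make(0.01, 0.01, Io=Io, sigma_noise=sigma_noise)
    return run_sweep(grid, spec, factory, n_trials, seed,
                     cell_fns=[slow_osc_power_cell], dt=dt,
                     record_dt=record_dt, protocol_tag=TAG_SLOW_OSC, **kw)


def run_coincident_sweep(grid: SweepGrid | None = None, n_trials: int = 4,
                         seed: int = 0, I1_amp: float = 0.5,
                         isi: float = 1000.0, Io: float = 0.32,
                         sigma_noise: float = 0.001, dt: float = 0.1,
                         record_dt: float = 1.0, **kw) -> SweepResult:
    """Cross-suppression sweep: delta_s1, crossing point and regime per cell."""
    if grid is None:
        grid = SweepGrid.full(10)
    program = coincident_series(I1_amp=I1_amp, isi=isi, dt=dt)

    def factory(rng: np.random.Generator) -> StimulusProgram:
        return program

    def cell_fn(traces, prog) -> dict:
        pk = [peak_trajectories(tr, prog.onsets) for tr in traces]
        p1 = np.mean([p[0] for p in pk], axis=0)
        p2 = np.mean([p[1] for p in pk], axis=0)
        labels = [classify_regime(tr, prog.onsets) for tr in traces]
        cx = crossing_index(p1, p2)
        return {"delta_s1": delta_s1(p1),
                "crossing": np.nan if cx is None else cx,
                "sustained": float(labels.count("sustained") > len(labels) / 2)}

    spec = ModelSpec.make(0.01, 0.01, Io=Io, sigma_noise=sigma_noise)
    return run_sweep(grid, spec, factory, n_trials, seed, cell_fns=[cell_fn],
                     dt=dt, record_dt=record_dt, protocol_tag=TAG_COINCIDENT,
                     **kw)
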