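"""Campaign configuration, execution and tabular output.

Each protocol (fig2/fig3/fig6/fig7/fig8/synth/metrics) has a fully
documented default :class:`RunConfig` reproducing the stated study settings;
:func:`run_protocol` executes it and writes a per-cell metric CSV, a JSON
run manifest (the resolved config, seed and package version — sufficient to
reproduce the run bit-exactly), and optionally the per-trial average-activity
traces in an ``.npz`` container.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiments import (SweepGrid, run_coincident, run_coincident_sweep,
                          run_fidelity_sweep, run_slow_osc_sweep)
from .metrics import (ResponseSet, io_correlation, paired_comparison,
                      response_amplitude, t50_model, t50_spikes,
                      band_power, tbt_reliability)
from .synthetic import (gen_lfp_session, gen_spike_session, lfp_response_set,
                        session_pair, spike_set, stimulus_reference)

log = logging.getLogger("twopop")

PROTOCOLS = ("fig2", "fig3", "fig6", "fig7", "fig8", "synth", "metrics")


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings of one campaign run (all defaults documented)."""
    protocol: str
    seed: int = 0
    out_dir: str = "runs"
    n_trials: int = 4
    dt: float = 0.1            # integration step, ms
    record_dt: float = 1.0     # trace sampling step, ms
    grid_n: int = 10           # points per coupling axis
    Io: float = 0.32           # background mean current, nA
    sigma_noise: float = 0.001  # background noise SD, nA
    sine_amp: float = 0.0      # slow-oscillation input amplitude, nA
    sine_freq: float = 2.0     # Hz
    n_amps: int = 10           # proportional-series amplitude count
    isi: float = 1000.0        # inter-stimulus interval, ms
    duration: float = 5000.0   # sinusoid-only trial length, ms
    I1_amp: float = 0.5        # coincident-series ensemble-1 amplitude, nA
    exemplars: tuple = ()      # (Js, Jo) pairs for exemplar protocols
    n_sessions: int = 7        # synthetic paired sessions
    in_path: str | None = None  # input container for the metrics protocol
    keep_traces: bool = False


_DEFAULTS = {
    "fig2": dict(n_trials=4, sigma_noise=0.001, isi=1000.0,
                 exemplars=((0.17, 0.01), (0.33, 0.33), (0.65, 0.33))),
    "fig3": dict(n_trials=4, sigma_noise=0.001, isi=1000.0),
    "fig6": dict(n_trials=4, sigma_noise=0.001, sine_amp=0.05),
    "fig7": dict(n_trials=20, sigma_noise=0.02, sine_amp=0.05, isi=400.0),
    "fig8": dict(n_trials=20, sigma_noise=0.02, sine_amp=0.0, isi=400.0),
    "synth": dict(),
    "metrics": dict(),
}


def default_config(protocol: str, **over) -> RunConfig:
    """The documented default configuration of a protocol."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; "
                         f"choose from {PROTOCOLS}")
    kw = dict(_DEFAULTS[protocol])
    kw.update(over)
    return RunConfig(protocol=protocol, **kw)


def load_config(path, protocol: str, **over) -> RunConfig:
    """Defaults for ``protocol`` overridden by a YAML mapping, then ``over``."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.pop("protocol", None)
    data.update(over)
    if "exemplars" in data:
        data["exemplars"] = tuple(tuple(e) for e in data["exemplars"])
    return default_config(protocol, **data)


def config_diff(a: RunConfig, b: RunConfig, ignore=("out_dir",)):
    """Names of the fields on which two configurations differ."""
    out = []
    for f in dataclasses.fields(RunConfig):
        if f.name in ignore:
            continue
        if getattr(a, f.name) != getattr(b, f.name):
            out.append(f.name)
    return sorted(out)


def _session_metrics_row(spec):
    lfp = gen_lfp_session(spec)
    spk = gen_spike_session(spec)
    rs = lfp_response_set(lfp)
    amp, tau = io_correlation(rs)
    return {
        "condition": spec.condition, "seed": spec.seed,
        "tbt_r": tbt_reliability(rs), "io_amp": amp, "io_tau_ms": tau,
        "t50_ms": t50_spikes(spike_set(spk)),
        "resp_amp": response_amplitude(rs),
        "power_2hz": float(np.mean([band_power(tr, lfp.fs, 2.0)
                                    for tr in lfp.lfp])),
    }


def run_protocol(config: RunConfig) -> dict:
    """Execute a campaign and write its outputs; returns the file paths."""
    if config.protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {config.protocol!r}")
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_test").write_text("")
        (out / ".write_test").unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} is not writable: {exc}")
    t0 = time.time()
    log.info("protocol %s started (seed=%d)", config.protocol, config.seed)

    traces_payload: dict[str, np.ndarray] = {}
    manifest_extra: dict = {}

    if config.protocol == "fig2":
        rows = []
        for Js, Jo in config.exemplars:
            res = run_coincident(Js, Jo, n_trials=config.n_trials,
                                 seed=config.seed, I1_amp=config.I1_amp,
                                 isi=config.isi, Io=config.Io,
                                 sigma_noise=config.sigma_noise,
                                 dt=config.dt, record_dt=config.record_dt)
            rows.append({"Js": Js, "Jo": Jo, "delta_s1": res["delta_s1"],
                         "crossing": (np.nan if res["crossing"] is None
                                      else res["crossing"]),
                         "regime": res["regime"]})
            if config.keep_traces:
                for q, tr in enumerate(res["traces"]):
                    traces_payload[f"Smean_Js{Js}_Jo{Jo}_trial{q}"] = tr.S_mean
        table = pd.DataFrame(rows)
    elif config.protocol == "fig3":
        sweep = run_coincident_sweep(SweepGrid.full(config.grid_n),
                                     n_trials=config.n_trials,
                                     seed=config.seed, I1_amp=config.I1_amp,
                                     isi=config.isi, Io=config.Io,
                                     sigma_noise=config.sigma_noise,
                                     dt=config.dt, record_dt=config.record_dt)
        table = sweep.table
    elif config.protocol == "fig6":
        sweep = run_slow_osc_sweep(SweepGrid.transient(config.grid_n),
                                   Io=config.Io,
                                   sigma_noise=config.sigma_noise,
                                   sine_amp=config.sine_amp,
                                   sine_freq=config.sine_freq,
                                   duration=config.duration,
                                   n_trials=config.n_trials, seed=config.seed,
                                   dt=config.dt, record_dt=config.record_dt)
        table = sweep.table
    elif config.protocol in ("fig7", "fig8"):
        with_sine = config.sine_amp > 0
        sweep = run_fidelity_sweep(SweepGrid.transient(config.grid_n),
                                   with_sine=with_sine,
                                   n_trials=config.n_trials, seed=config.seed,
                                   n_amps=config.n_amps, isi=config.isi,
                                   Io=config.Io,
                                   sigma_noise=config.sigma_noise,
                                   sine_amp=config.sine_amp,
                                   sine_freq=config.sine_freq, dt=config.dt,
                                   record_dt=config.record_dt,
                                   keep_traces=config.keep_traces)
        table = sweep.table
        if config.keep_traces and sweep.traces:
            for (i, j), trs in sweep.traces.items():
                for q, tr in enumerate(trs):
                    traces_payload[f"Smean_cell{i}_{j}_trial{q}"] = tr.S_mean
        manifest_extra["grid_means"] = {
            m: float(np.nanmean(table[m]))
            for m in ("tbt_r", "io_amp", "io_tau_ms", "t50_ms", "resp_amp")
            if m in table}
    elif config.protocol == "synth":
        rows = []
        for k in range(config.n_sessions):
            ctrl, mod = session_pair(seed=config.seed + k)
            rows.append(_session_metrics_row(ctrl))
            rows.append(_session_metrics_row(mod))
        table = pd.DataFrame(rows)
        tests = {}
        for m in ("tbt_r", "io_amp", "io_tau_ms", "t50_ms", "power_2hz"):
            c = table[table.condition == "control"][m].to_numpy()
            d = table[table.condition == "modulated"][m].to_numpy()
            t, p, df = paired_comparison(c, d)
            tests[m] = {"t": t, "p": p, "df": df}
        manifest_extra["paired_tests"] = tests
        # first session's LFP, in the container the metrics protocol reads
        first = gen_lfp_session(session_pair(seed=config.seed)[0])
        traces_payload.update({
            "trials": -first.lfp, "stimulus": stimulus_reference(first.truth),
            "fs": np.array(first.fs), "events": first.events})
    elif config.protocol == "metrics":
        if not config.in_path:
            raise ValueError("the metrics protocol requires in_path "
                             "(an .npz with trials/stimulus/fs/events)")
        with np.load(config.in_path) as z:
            rs = ResponseSet(fs=float(z["fs"]), trials=z["trials"],
                             stimulus_waveform=z["stimulus"],
                             event_times=z["events"])
        row = {}
        from .metrics import UndefinedMetricError
        for name, fn in (("tbt_r", tbt_reliability),
                         ("io_amp", lambda r: io_correlation(r)[0]),
                         ("io_tau_ms", lambda r: io_correlation(r)[1]),
                         ("t50_ms", t50_model),
                         ("resp_amp", response_amplitude)):
            try:
                row[name] = fn(rs)
            except UndefinedMetricError as exc:
                log.warning("metric %s undefined: %s", name, exc)
                row[name] = np.nan
        table = pd.DataFrame([row])

    paths = {}
    csv_path = out / f"{config.protocol}_table.csv"
    table.to_csv(csv_path, index=False)
    paths["table"] = str(csv_path)
    manifest = {"config": dataclasses.asdict(config),
                "version": __version__, "seed": config.seed}
    manifest.update(manifest_extra)
    man_path = out / f"{config.protocol}_manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, default=list))
    paths["manifest"] = str(man_path)
    if traces_payload:
        npz_path = out / f"{config.protocol}_traces.npz"
        np.savez_compressed(npz_path, **traces_payload)
        paths["traces"] = str(npz_path)
    log.info("protocol %s finished in %.1f s -> %s", config.protocol,
             time.time() - t0, csv_path)
    return paths
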