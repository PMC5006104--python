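"""Paired control vs feedback-modulated surrogate recording sessions.

Generates matched synthetic LFP/MUA sessions (the modulated condition has
half the 1-4 Hz slow-oscillation power and a faster evoked kernel), runs
the full metric battery on each, and applies the paired t test across
sessions — the same workflow used on in vivo recordings, but with known
ground truth.
"""

import numpy as np

from twopop.metrics import (band_power, io_correlation, paired_comparison,
                            t50_spikes, tbt_reliability)
from twopop.synthetic import (gen_lfp_session, gen_spike_session,
                              lfp_response_set, session_pair, spike_set)

n_sessions = 7
rows = {"control": {}, "modulated": {}}
for metric in ("tbt_r", "io_amp", "io_tau_ms", "t50_ms", "power_2hz"):
    rows["control"][metric] = []
    rows["modulated"][metric] = []

for k in range(n_sessions):
    for cond, spec in zip(("control", "modulated"), session_pair(seed=k)):
        lfp = gen_lfp_session(spec)
        rs = lfp_response_set(lfp)
        amp, tau = io_correlation(rs)
        rows[cond]["tbt_r"].append(tbt_reliability(rs))
        rows[cond]["io_amp"].append(amp)
        rows[cond]["io_tau_ms"].append(tau)
        rows[cond]["t50_ms"].append(
            t50_spikes(spike_set(gen_spike_session(spec))))
        rows[cond]["power_2hz"].append(
            float(np.mean([band_power(x, lfp.fs, 2.0) for x in lfp.lfp])))

print(f"paired t tests over {n_sessions} sessions (modulated vs control):")
for metric in rows["control"]:
    c = rows["control"][metric]
    m = rows["modulated"][metric]
    t, p, df = paired_comparison(c, m)
    print(f"  {metric:10s}: {np.mean(c):8.3f} -> {np.mean(m):8.3f}   "
          f"t({df}) = {t:+.2f}, p = {p:.2g}")

print("\nReliability and I-O amplitude rise while I-O tau, T50 and 2 Hz "
      "power fall — the signature of the feedback-modulated condition, "
      "recovered from the surrogate data.")
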