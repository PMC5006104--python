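"""Compiled integration kernel for the two-ensemble circuit.

The kernel advances a batch of independent simulations (one per row of the
state arrays) with a shared transient-stimulus waveform and per-simulation
sinusoid phase and noise stream.  Batching across trials/grid cells is what
makes desk-scale parameter sweeps fast; a single trial is just a batch of
size one, so both paths are bit-identical by construction.

All times are milliseconds, currents nA, rates Hz.  The gating equation is
integrated per-ms, so the Hz rate is scaled by 1e-3 inside the loop.
"""

import math

from numba import njit

_TWO_PI = 2.0 * math.pi
#: |a*I - b| below which the transfer function switches to its Taylor limit.
SINGULARITY_TOL = 1e-6


@njit(cache=False)
def _rate(I, a, b, d):
    x = a * I - b
    if abs(x) < SINGULARITY_TOL:
        # removable singularity: x/(1-exp(-d*x)) -> 1/d + x/2 as x -> 0
        return 1.0 / d + 0.5 * x
    return x / (1.0 - math.exp(-d * x))


@njit(cache=False)
def _integrate(S, N, Js, Jo, trans1, trans2, sine_amp, sine_freq, phases, z,
               a, b, d, gamma, tau_s, tau_n, Io, sigma, dt,
               burn_steps, stride, S1o, S2o, N1o, N2o, diag):
    """Euler-Maruyama integration of the coupled gating + OU-noise system.

    State arrays ``S`` (gating) and ``N`` (noise currents) have shape
    ``(m, 2)`` and are updated in place.  ``trans1``/``trans2`` hold the
    shared transient input for t >= 0; during the ``burn_steps`` preceding
    steps the transient is zero but the sinusoid and noise run, so the
    recorded trace starts from an equilibrated state.  Recording happens
    every ``stride`` steps into the ``(m, n_rec)`` output arrays.

    ``diag[0]`` receives the largest gating-bound overshoot seen (caller
    decides whether it is tolerable), ``diag[1]`` the first step index at
    which the state became non-finite, or -1.
    """
    m = S.shape[0]
    n_main = trans1.shape[0]
    n_total = burn_steps + n_main
    alpha = dt / tau_n
    cnoise = sigma * math.sqrt(2.0 * dt / tau_n)
    w = _TWO_PI * sine_freq * 1e-3  # rad per ms
    max_over = 0.0
    for k in range(n_total):
        km = k - burn_steps
        if km >= 0 and km % stride == 0:
            j = km // stride
            for i in range(m):
                S1o[i, j] = S[i, 0]
                S2o[i, j] = S[i, 1]
                N1o[i, j] = N[i, 0]
                N2o[i, j] = N[i, 1]
        if km >= 0:
            st1 = trans1[km]
            st2 = trans2[km]
        else:
            st1 = 0.0
            st2 = 0.0
        t_ms = km * dt
        for i in range(m):
            sv = 0.0
            if sine_amp != 0.0:
                sv = sine_amp * math.sin(w * t_ms + phases[i])
            I1 = Js[i] * S[i, 0] - Jo[i] * S[i, 1] + st1 + sv + N[i, 0]
            I2 = Js[i] * S[i, 1] - Jo[i] * S[i, 0] + st2 + sv + N[i, 1]
            r1 = _rate(I1, a, b, d)
            r2 = _rate(I2, a, b, d)
            s1 = S[i, 0] + dt * (-S[i, 0] / tau_s
                                 + (1.0 - S[i, 0]) * gamma * r1 * 1e-3)
            s2 = S[i, 1] + dt * (-S[i, 1] / tau_s
                                 + (1.0 - S[i, 1]) * gamma * r2 * 1e-3)
            if s1 != s1 or s2 != s2:  # NaN
                diag[0] = max_over
                diag[1] = float(k)
                return
            if s1 > 1.0:
                if s1 - 1.0 > max_over:
                    max_over = s1 - 1.0
                s1 = 1.0
            elif s1 < 0.0:
                if -s1 > max_over:
                    max_over = -s1
                s1 = 0.0
            if s2 > 1.0:
                if s2 - 1.0 > max_over:
                    max_over = s2 - 1.0
                s2 = 1.0
            elif s2 < 0.0:
                if -s2 > max_over:
                    max_over = -s2
                s2 = 0.0
            S[i, 0] = s1
            S[i, 1] = s2
            if cnoise != 0.0:
                N[i, 0] = N[i, 0] + alpha * (Io - N[i, 0]) + cnoise * z[i, k, 0]
                N[i, 1] = N[i, 1] + alpha * (Io - N[i, 1]) + cnoise * z[i, k, 1]
            else:
                N[i, 0] = N[i, 0] + alpha * (Io - N[i, 0])
                N[i, 1] = N[i, 1] + alpha * (Io - N[i, 1])
    diag[0] = max_over
    diag[1] = -1.0
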