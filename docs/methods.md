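# Methods

## Model

The circuit is the two-variable mean-field reduction of a network with two
recurrent excitatory populations and shared global inhibition.  Each
ensemble carries one synaptic gating variable `S` (dimensionless, 0–1)
standing in for its population activity; the inhibitory population is not
resolved but folded into the effective couplings.  `Js` is the net
within-ensemble coupling (recurrent excitation minus feedback inhibition,
`Js >= 0`), `Jo` the magnitude of the net between-ensemble coupling
(lateral inhibition dominating cross-excitation; it enters the input with
a minus sign).  Both couplings are identical for the two ensembles
(symmetric circuit).  The transfer function `f(I) = (aI-b)/(1-exp(-d(aI-b)))`
(a = 270 Hz/nA, b = 108 Hz, d = 0.154 s) is strictly positive and strictly
increasing; its removable singularity at `aI = b` is evaluated by the
two-term Taylor limit `1/d + (aI-b)/2` whenever `|aI-b| < 1e-6`.
Background drive is an independent Ornstein–Uhlenbeck current per
ensemble with mean `Io`, SD `sigma_noise` and correlation time 10 ms.
Gating follows `dS/dt = -S/tau_s + (1-S)*gamma*r` with `gamma = 0.641`
and `tau_s = 100` ms.

Assumptions worth keeping in mind: the model has no intrinsic rhythm (the
slow oscillation must be supplied as input), excitation and inhibition act
coincidently, and `S` reflects excitatory activity only.

## Numerical scheme

* Explicit Euler–Maruyama, `dt = 0.1` ms by default (a config knob); a
  step-halving convergence check is part of the test suite.  Internal time
  is ms, currents nA, rates Hz (the `gamma*r` term is scaled by `1e-3`
  inside the per-ms update; `gating_derivative` exposes the same quantity
  in 1/s).
* OU discretization: increment `sigma*sqrt(2*dt/tau)*z` with
  `z ~ N(0,1)`, chosen so the stationary SD of the continuum process
  equals `sigma_noise` — this makes `sigma_noise` directly interpretable
  and testable.  The discrete chain's stationary SD is inflated by
  `(1 - dt/(2 tau))^-1/2`, about 0.25% at the default step.  Conventions
  that scale the white-noise term differently change the effective noise
  by a constant factor; this contract is the one the package guarantees.
* Initial state: both gating variables start at the closed-form fixed
  point of the gating equation at the background rate `f(Io)`, followed by
  a 500 ms burn-in (noise and sinusoid on, transients off) before t = 0.
* `S` is clipped to [0, 1] only for numerical overshoot below `1e-6`;
  anything larger raises an integration error rather than being silently
  truncated, so step-size problems surface immediately.
* The batch integrator (numba) advances all trials of a grid cell at
  once; a single trial is a batch of one, so sweep cells and direct
  `integrate_trial` calls are bit-identical given the same derived seed.

## Stimulus protocols

* Transient stimuli: 10 ms rectangular pulses filtered by a first-order
  low-pass with a 10 ms time constant (exact exponential smoothing, unit
  DC gain).  Coincident series: 13 simultaneous pulse pairs, ensemble 1
  fixed at 0.5 nA, ensemble 2 at ratios 0–4 in steps of 1/3, so the
  equal-input condition is stimulus 4 (1-based).  Proportional series:
  `Istim2 = 0.6 * Istim1` with 10 amplitudes linearly spaced over
  0.06–0.6 nA, ascending.
* Inter-stimulus intervals are not uniquely determined by the protocols'
  definitions; the defaults are 1000 ms for the coincident series and
  400 ms for the proportional series — long enough for transient-regime
  decay, short enough to keep sweeps at desk scale — and both are
  configurable.
* The slow-oscillation surrogate is a 2 Hz, 0.05 nA sinusoid applied
  identically to both ensembles, phase drawn uniformly per trial.
* Noise settings per protocol: coincident and sinusoid-only runs use
  `Io = 0.32` nA, `sigma_noise = 0.001` nA; the proportional (sensory)
  protocol uses `Io = 0.32` nA, `sigma_noise = 0.02` nA.

## Sweeps and seeding

Coupling grids cover the full range (Js 0.01–0.74, Jo 0.01–0.37 nA) or
the transient-response range (both 0.01–0.37 nA), 10 points per axis by
default.  Grid-averaged metrics depend mildly on grid resolution; the
grid size is a config knob (`--grid-n`).  Every trial's generator derives
from `SeedSequence((master, protocol, i_js, i_jo, trial))`, so cells are
independent, order-free, and reproducible; diverged trials are dropped
and counted per cell without aborting the sweep.  Metric estimation uses
20 trials per cell by default (4-trial figure-style runs remain
available).

## Analysis definitions

* TbT reliability: mean Pearson correlation at zero lag over all
  unordered pairs of single-trial traces; constant trials are excluded
  with a warning.
* I–O correlogram: Pearson correlation between the filtered transient
  input waveform (the reference is the input actually delivered, without
  the sinusoid) and each single-trial `(S1+S2)/2` trace at response lags
  0–100 ms.  I–O amp is the mean over trials of the per-trial peak; I–O
  tau is the decay constant of `A*exp(-(lag-lag_peak)/tau)` least-squares
  fitted to the trial-averaged correlogram from its peak to the 100 ms
  lag (log-linear fallback when the nonlinear fit fails on an
  all-positive tail; failures raise, never silently default).
* T50 (continuous traces): event-aligned responses, baseline = mean of
  the 50 ms pre-event window, averaged over all events and trials; the
  normalized cumulative profile over 0–100 ms post-stimulus is
  interpolated linearly at 0.5.  A net-negative profile, or one whose
  cumulative drawdown exceeds 25% of its final value, is treated as
  undefined (strict monotonicity is unattainable for stochastic traces).
* T50 (spike trains): pooled peri-stimulus spike latencies within
  10–80 ms (the lower edge absorbing conduction delay); the reported
  value is the interpolated median — exactly the 0.5 point of the
  normalized cumulative count without histogram quantization.
* Band power: multitaper PSD (DPSS tapers, time–bandwidth product 4,
  7 tapers) at the bin containing the target frequency, mean removed; a
  Hann periodogram is available for short traces and flagged by the
  `method` argument.
* Crossing index: first 1-based stimulus at which ensemble 2's peak
  reaches ensemble 1's, with a 0.01 tie tolerance — at the equal-input
  stimulus the trajectories intersect, and a strict comparison would
  resolve the tie by noise.
* Regime label: "sustained" iff after some stimulus `max(S1, S2)` stays
  above 0.3 for at least 80% of the interval to the next stimulus; both
  threshold and dwell fraction are configurable.
* LFP preprocessing: zero-phase 4th-order Butterworth at 100 Hz, then
  resampling to 200 Hz (stride decimation for integer ratios, polyphase
  otherwise).  Requires an input rate of at least 400 Hz.

## Dynamical structure of the default model

The gating fixed points can be read off `steady_state_gating(firing_rate(I))`
self-consistently, and they shape every campaign:

* With `Io = 0.32` nA, a stable lone-active (winner-take-all) state —
  one ensemble high, the competitor silenced — exists down to roughly
  `Js ≈ 0.27`, so moderate-coupling circuits such as (Js, Jo) =
  (0.33, 0.33) are already bistable: a single strong pulse leaves
  persistent activity (covered by a unit test).  Consequently the
  cross-suppression index of such circuits is large (the last-stimulus
  response is suppressed by a persistent winner) and their S1–S2 crossing
  is strongly right-shifted.
* For net self-coupling `Js - Jo` above roughly 0.30 the quiet symmetric
  baseline disappears entirely and both ensembles drift to a co-elevated
  state within a second or two; high-`Js`/low-`Jo` cells therefore
  operate around an elevated set point with fast local kinetics, while
  balanced or inhibition-dominated cells stay quiet.
* The linearized gating time constant is `1/(1/tau_s + gamma*r)`:
  about 95 ms at the quiet baseline (`r ≈ 0.8` Hz) and about 30 ms in
  elevated states (`r ≈ 30–40` Hz).  Grid-averaged I–O tau and T50 are
  therefore dominated by how many cells of the grid sit quiet versus
  elevated, and are sensitive to `tau_s` and `Io` well beyond their
  formal roles; published analyses of closely related models report
  faster grid-averaged time constants than the quiet-baseline kinetics of
  this parameterization can produce.  The package deliberately keeps the
  canonical constants rather than retrofitting effective ones.

## Synthetic sessions

The generator emulates the statistical structure of anesthetized-cortex
recordings, not their magnitudes: an LFP-like trace = band-limited
random-phase 1–4 Hz process (SD = `slow_osc_power`) + per-event
difference-of-exponentials kernels (negative-deflecting, per the cortical
LFP sign convention; the analysis path inverts the sign before
stimulus–response correlation) + white noise; an MUA-like inhomogeneous
Poisson train from a baseline rate plus an event-locked alpha-shaped rate
kernel starting 10 ms post-stimulus.  Event amplitudes cycle through ten
levels (0.1–1.0), mirroring graded stimulus intensities; the event
schedule is fixed but deliberately irregular, because a regular interval
inside the 1–4 Hz band would phase-lock the slow oscillation to the
events and bias event-aligned averages.  The "modulated" condition halves
the slow-oscillation power and shortens the evoked kernel (25 → 15 ms),
so all five metrics shift in known directions; the tests require the
correct sign in at least 95% of 20 seeded replicates.  What passing these
tests shows is that the analysis battery recovers known ground-truth
directions from realistic-looking surrogates — not that the generator
reproduces any particular recording.

## Problem sizes

Defaults were chosen so every campaign runs on one CPU in minutes: 10×10
coupling grids with 20 trials per cell for the sensory-fidelity sweeps
(4.2 s trials, 0.1 ms steps), 4 trials for figure-style exemplar runs,
5 s sinusoid-only trials for band power, 20-trial synthetic sessions of
3 s.  All sizes are config knobs.

## Known limitations

* The model cannot generate a slow oscillation intrinsically; 2 Hz
  propagation results describe forced-response gain only.
* The exponential correlogram fit has no offset term; correlograms that
  decay to a nonzero plateau within the 100 ms lag window yield long
  fitted time constants by construction.
* Response amplitude uses the excitatory gating variable only, so it
  cannot capture measurements that mix excitatory and inhibitory spiking.
* The paired-comparison workflow is exercised on synthetic sessions; no
  claims are made about in vivo effect sizes.
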