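"""Unit and property tests for the circuit model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twopop import (Couplings, GatingParams, ModelSpec, NoiseSpec,
                    TransferParams, firing_rate, gating_derivative,
                    integrate_trial, steady_state_gating, step_ou_noise,
                    total_inputs)
from twopop.stimuli import StimulusProgram, coincident_series

finite_floats = st.floats(min_value=-10, max_value=10, allow_nan=False)


class TestFiringRate:
    def test_removable_singularity_limit(self, transfer):
        # at a*I = b the transfer function equals 1/d exactly
        assert firing_rate(transfer.b / transfer.a, transfer) == pytest.approx(
            1.0 / transfer.d, rel=1e-9)

    def test_reference_values(self, transfer):
        # frozen from direct scalar evaluation of the closed form
        assert firing_rate(0.0, transfer) == pytest.approx(6.4613e-6, rel=1e-3)
        # linear asymptote: the exponential term is negligible at 1 nA
        assert firing_rate(1.0, transfer) == pytest.approx(162.0, abs=1e-6)

    def test_strictly_increasing_on_grid(self, transfer):
        I = np.linspace(-1.0, 2.0, 1000)
        r = firing_rate(I, transfer)
        assert np.all(r > 0)
        assert np.all(np.diff(r) > 0)

    def test_continuous_across_singularity(self, transfer):
        I0 = transfer.b / transfer.a
        for eps in (1e-10, 1e-8, 3e-9):
            lo = firing_rate(I0 - eps, transfer)
            hi = firing_rate(I0 + eps, transfer)
            assert lo == pytest.approx(1 / transfer.d, abs=1e-5)
            assert hi == pytest.approx(1 / transfer.d, abs=1e-5)

    def test_nonfinite_input_rejected(self, transfer):
        with pytest.raises(ValueError):
            firing_rate(np.nan, transfer)
        with pytest.raises(ValueError):
            firing_rate(np.inf, transfer)


class TestTotalInputs:
    def test_zero_case(self):
        assert total_inputs(0, 0, Couplings(0.3, 0.1)) == (0.0, 0.0)

    def test_self_and_cross_cancellation(self):
        # Js = Jo with S1 = S2 cancels the coupling terms exactly
        I1, I2 = total_inputs(0.5, 0.5, Couplings(0.35, 0.35),
                              Inoise1=0.32, Inoise2=0.32)
        assert I1 == pytest.approx(0.32) and I2 == pytest.approx(0.32)

    def test_hand_arithmetic(self):
        I1, I2 = total_inputs(1.0, 0.0, Couplings(0.33, 0.01))
        assert I1 == pytest.approx(0.33) and I2 == pytest.approx(-0.01)

    @settings(max_examples=50, deadline=None)
    @given(s1=st.floats(0, 1), s2=st.floats(0, 1), a1=finite_floats,
           a2=finite_floats, n1=finite_floats, n2=finite_floats)
    def test_label_exchange_symmetry(self, s1, s2, a1, a2, n1, n2):
        c = Couplings(0.4, 0.2)
        I1, I2 = total_inputs(s1, s2, c, a1, a2, n1, n2)
        J2, J1 = total_inputs(s2, s1, c, a2, a1, n2, n1)
        assert I1 == J1 and I2 == J2


class TestOUNoise:
    def test_fixed_point_at_mean(self):
        spec = NoiseSpec(Io=0.3, sigma_noise=0.0)
        assert step_ou_noise(0.3, spec, dt=0.1, z=0.0) == pytest.approx(0.3)

    def test_one_step_deterministic_decay(self):
        spec = NoiseSpec(Io=0.3, sigma_noise=0.0, tau_noise=10.0)
        assert step_ou_noise(1.3, spec, dt=1.0, z=0.0) == pytest.approx(
            0.3 + 0.9)

    def test_large_step_warns(self):
        spec = NoiseSpec(Io=0.3, sigma_noise=0.0, tau_noise=10.0)
        with pytest.warns(UserWarning):
            step_ou_noise(0.3, spec, dt=10.0, z=0.0)

    def test_stationary_mean_and_sd(self, rng):
        # contract: long-run SD equals sigma_noise. With N steps of dt=0.1
        # and tau=10 ms the effective sample count is Neff = N*dt/(2*tau)
        # = 1500, so SE(mean) ~ sigma/sqrt(Neff) ~ 5e-4 and SE(SD) ~
        # sigma/sqrt(2*Neff) ~ 0.018*sigma; allow ~3 SE plus the 0.25%
        # discretization bias.
        spec = NoiseSpec(Io=0.32, sigma_noise=0.02, tau_noise=10.0)
        n = 300_000
        z = rng.standard_normal(n)
        x = np.empty(n)
        v = spec.Io
        for k in range(n):
            v = step_ou_noise(v, spec, 0.1, z[k])
            x[k] = v
        assert x.mean() == pytest.approx(0.32, abs=2e-3)
        assert x.std() == pytest.approx(0.02, rel=0.06)

    def test_autocorrelation_time(self, rng):
        # same recursion via lfilter for a 1e6-step run; the ACF decay time
        # must recover tau_noise within 20 %
        from scipy.signal import lfilter
        tau, dt, sigma = 10.0, 0.1, 0.02
        alpha = dt / tau
        c = sigma * math.sqrt(2 * dt / tau)
        x = lfilter([c], [1, -(1 - alpha)], rng.standard_normal(1_000_000))
        lags = np.arange(1, 400)
        x0 = x - x.mean()
        acf = np.array([np.dot(x0[:-k], x0[k:]) / np.dot(x0, x0)
                        for k in lags])
        good = acf > 0.05
        slope = np.polyfit(lags[good] * dt, np.log(acf[good]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.2)


class TestGating:
    def test_derivative_reference_points(self):
        g = GatingParams()
        assert gating_derivative(0.0, 0.0, g) == 0.0
        assert gating_derivative(1.0, 50.0, g) == pytest.approx(-10.0)
        assert gating_derivative(0.5, 10.0, g) == pytest.approx(-1.795)

    def test_steady_state_values_and_consistency(self):
        g = GatingParams()
        assert steady_state_gating(0.0, g) == 0.0
        assert steady_state_gating(10.0, g) == pytest.approx(0.641 / 1.641,
                                                             rel=1e-9)
        assert steady_state_gating(1e6, g) > 0.9999
        for r in (0.5, 3.0, 40.0):
            s = steady_state_gating(r, g)
            assert gating_derivative(s, r, g) == pytest.approx(0.0, abs=1e-9)


def _program(dt=0.1, duration=2000.0, sine_amp=0.0, events=()):
    return StimulusProgram(dt=dt, duration=duration, events=events,
                           sine_amp=sine_amp)


class TestIntegrateTrial:
    def test_zero_drive_stays_near_zero(self):
        # with no background, no stimulus and no noise, the tiny baseline
        # rate f(0) keeps S below 1e-3 indefinitely
        spec = ModelSpec.make(0.2, 0.1, Io=0.0, sigma_noise=0.0)
        tr = integrate_trial(spec, _program(), seed=0)
        assert np.all(tr.S1 < 1e-3) and np.all(tr.S2 < 1e-3)

    def test_symmetric_inputs_give_identical_ensembles(self):
        spec = ModelSpec.make(0.3, 0.2, Io=0.32, sigma_noise=0.0)
        prog = _program(sine_amp=0.05,
                        events=((500.0, 0.3, 0.3), (1200.0, 0.5, 0.5)))
        tr = integrate_trial(spec, prog, seed=0)
        assert np.array_equal(tr.S1, tr.S2)

    def test_swapped_stimuli_swap_outputs_exactly(self):
        spec = ModelSpec.make(0.3, 0.2, Io=0.32, sigma_noise=0.0)
        ev = ((500.0, 0.4, 0.1), (1200.0, 0.2, 0.5))
        ev_sw = tuple((t, a2, a1) for t, a1, a2 in ev)
        tr = integrate_trial(spec, _program(events=ev), seed=0)
        sw = integrate_trial(spec, _program(events=ev_sw), seed=0)
        assert np.array_equal(tr.S1, sw.S2) and np.array_equal(tr.S2, sw.S1)

    def test_seed_reproducibility_and_bounds(self):
        spec = ModelSpec.make(0.33, 0.33, Io=0.32, sigma_noise=0.02)
        prog = _program(sine_amp=0.05, events=((500.0, 0.5, 0.3),))
        a = integrate_trial(spec, prog, seed=7)
        b = integrate_trial(spec, prog, seed=7)
        c = integrate_trial(spec, prog, seed=8)
        for x, y in ((a.S1, b.S1), (a.S2, b.S2), (a.Inoise1, b.Inoise1)):
            assert np.array_equal(x, y)
        assert not np.array_equal(a.S1, c.S1)
        for s in (a.S1, a.S2):
            assert np.all(s >= 0.0) and np.all(s <= 1.0)

    def test_s_mean_recomputable(self):
        spec = ModelSpec.make(0.2, 0.1, Io=0.32, sigma_noise=0.01)
        tr = integrate_trial(spec, _program(), seed=3)
        assert np.array_equal(tr.S_mean, (tr.S1 + tr.S2) / 2.0)

    def test_dt_halving_convergence(self):
        # deterministic run: halving the step changes the trace by < 1e-3
        spec = ModelSpec.make(0.3, 0.2, Io=0.32, sigma_noise=0.0)
        kw = dict(duration=2000.0, record_dt=1.0, seed=0)
        t1 = integrate_trial(spec, _program(dt=0.1, sine_amp=0.05,
                                            events=((500.0, 0.5, 0.3),)),
                             dt=0.1, **kw)
        t2 = integrate_trial(spec, _program(dt=0.05, sine_amp=0.05,
                                            events=((500.0, 0.5, 0.3),)),
                             dt=0.05, **kw)
        assert np.max(np.abs(t1.S1 - t2.S1)) < 1e-3
        assert np.max(np.abs(t1.S2 - t2.S2)) < 1e-3


class TestBistability:
    """Persistence structure of exemplar circuits under a single pulse.

    Note: with the default constants and Io = 0.32 nA background, a lone
    winner-take-all state exists down to Js ~ 0.27, so persistence is probed
    at a strongly recurrent exemplar and decay at a weakly recurrent one.
    """

    def test_strong_recurrence_sustains_winner(self):
        # the pulse arrives while the network is still near its quiet
        # initial state, so the stimulated ensemble wins and its activity
        # outlasts the stimulus by >= 1 s while the other is suppressed
        spec = ModelSpec.make(0.65, 0.33, Io=0.32, sigma_noise=0.001)
        prog = _program(duration=2500.0, events=((200.0, 0.5, 0.0),))
        tr = integrate_trial(spec, prog, seed=0, burn_in=0.0,
                             S_init=(0.05, 0.05))
        late = (tr.t > 1210.0) & (tr.t < 2400.0)  # >= 1 s after offset
        assert np.all(tr.S1[late] > 0.3)
        assert np.all(tr.S2[late] < tr.S1[late])

    def test_moderate_recurrence_also_bistable(self):
        # the lone-active branch extends to moderate couplings: at
        # Js = 0.33 a strong pulse still leaves persistent activity, i.e.
        # the persistence boundary of this model lies below Js = 0.33
        spec = ModelSpec.make(0.33, 0.33, Io=0.32, sigma_noise=0.001)
        prog = _program(duration=2500.0, events=((200.0, 0.5, 0.0),))
        tr = integrate_trial(spec, prog, seed=0, burn_in=0.0,
                             S_init=(0.05, 0.05))
        assert np.all(tr.S1[tr.t > 1210.0] > 0.3)

    def test_weak_recurrence_decays_to_baseline(self):
        spec = ModelSpec.make(0.17, 0.01, Io=0.32, sigma_noise=0.001)
        prog = _program(duration=3000.0, events=((500.0, 0.5, 0.0),))
        tr = integrate_trial(spec, prog, seed=0)
        base = tr.S1[tr.t < 450].mean()
        assert np.all(tr.S1[(tr.t > 1510.0)] < base + 0.05)


class TestValidation:
    def test_negative_couplings_rejected(self):
        with pytest.raises(ValueError):
            Couplings(-0.1, 0.2)
        with pytest.raises(ValueError):
            Couplings(0.1, -0.2)

    def test_bad_gating_params_rejected(self):
        with pytest.raises(ValueError):
            GatingParams(gamma=0.0)
        with pytest.raises(ValueError):
            GatingParams(tau_s=-1.0)

    def test_program_must_cover_duration(self, quiet_spec):
        with pytest.raises(ValueError):
            integrate_trial(quiet_spec, _program(duration=100.0),
                            duration=500.0, seed=0)
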