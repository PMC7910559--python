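"""Simulator tests: master-equation integration, artifact model, and the
consistency of simulated currents with the equilibrium gating curve."""

import numpy as np
import pytest

from hvkit import (
    ChannelModel,
    GatingScheme,
    NoiseRundown,
    Solutions,
    estimate_reversal,
    nernst_potential,
    open_probability_course,
    reversal_protocol,
    simulate_recording,
    standard_step_protocol,
    state_probability_course,
    steady_state_po,
    subtract_leak,
    tail_iv,
)
from hvkit.model import transition_rates
from hvkit.protocol import Epoch, VoltageProtocol, ramp_protocol


def single_step_protocol(v_hold, v_step, duration, dt=1.0, n_sweeps=1):
    return VoltageProtocol(
        segments=(
            Epoch("hold", v_hold, v_hold, 50.0),
            Epoch("step", v_step, v_step, duration),
        ),
        n_sweeps=n_sweeps,
        dt=dt,
    )


class TestOccupancyConservation:
    def test_step_and_ramp_protocols(self, three_state_model):
        for protocol in (
            standard_step_protocol(n_sweeps=2),
            ramp_protocol(ramp_duration=500.0, v_prepulse=40.0),
        ):
            course = state_probability_course(three_state_model, protocol)
            total = course.sum(axis=1)
            assert np.max(np.abs(total - 1.0)) < 1e-9
            assert np.all(course >= -1e-12)


class TestAsymptoticConsistency:
    @pytest.mark.parametrize("preset_fixture", ["slhv1", "aohv1", "slhv1_seq"])
    def test_terminal_po_reaches_equilibrium(self, preset_fixture, request):
        model = request.getfixturevalue(preset_fixture)
        sol = Solutions()
        v = model.v_half_ref + 10.0
        protocol = single_step_protocol(-80.0, v, duration=4000.0, dt=2.0)
        po = open_probability_course(model, protocol, sol)
        assert po[-1] == pytest.approx(steady_state_po(v, model, sol), abs=1e-3)


class TestTwoStateRelaxation:
    def test_relaxation_rate_is_sum_of_rates(self, slhv1):
        """The fitted exponential rate of a step response must equal the
        analytic two-state relaxation 1/(alpha + beta)."""
        sol = Solutions()
        v = 60.0
        alpha, beta = transition_rates(v, slhv1, sol)
        tau_expected = 1.0 / float(alpha[0] + beta[0])
        protocol = single_step_protocol(-80.0, v, duration=6 * tau_expected, dt=1.0)
        po = open_probability_course(slhv1, protocol, sol)
        step = po[50:]  # step epoch starts at sample 50
        p_inf = steady_state_po(v, slhv1, sol)
        # log-linear fit of the residual decay
        resid = p_inf - step
        keep = resid > 1e-12
        t = np.arange(step.size)[keep] * 1.0
        slope = np.polyfit(t, np.log(resid[keep]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau_expected, rel=1e-6)


class TestActivationLag:
    def test_multistate_scheme_shows_sigmoidal_onset(self, slhv1_seq, slhv1):
        """With more than one closed state the activation time course is
        sigmoidal: the initial slope is ~0 and the curvature positive."""
        sol = Solutions()
        proto = single_step_protocol(-80.0, 60.0, duration=400.0, dt=0.5)
        po3 = open_probability_course(slhv1_seq, proto, sol)[100:]
        po2 = open_probability_course(slhv1, proto, sol)[100:]
        d3 = np.diff(po3[:20])
        d2 = np.diff(po2[:20])
        # three-state: rising derivative (lag); two-state: maximal at onset
        assert d3[0] < d3[-1]
        assert d2[0] > d2[-1]


class TestSimulatedCurrents:
    def test_zero_conductance_leaves_pure_leak(self):
        model = ChannelModel(g_max=0.0, v_half_ref=0.0, s=8.0)
        protocol = standard_step_protocol(n_sweeps=2)
        nr = NoiseRundown(sigma_I=0.0, rundown_per_sweep=1.0, g_leak=0.5, E_leak=-10.0)
        rec = simulate_recording(model, protocol, Solutions(), nr)
        expected = 0.5 * (rec.voltages - (-10.0))
        assert np.allclose(rec.currents, expected)

    def test_terminal_current_matches_equilibrium(self, clean_recording, slhv1):
        sol = clean_recording.solutions
        sl = clean_recording.epoch_slice(4)
        for sweep in (8, 10, 12):
            v = clean_recording.protocol.epoch_voltage(4, sweep)[0]
            i_end = clean_recording.currents[sweep, sl][-5:].mean()
            expected = slhv1.g_max * steady_state_po(v, slhv1, sol) * (v - 0.0)
            assert i_end == pytest.approx(expected, rel=2e-3, abs=0.5)

    def test_rundown_scales_geometrically(self, slhv1):
        protocol = standard_step_protocol(n_sweeps=3)
        nr = NoiseRundown(sigma_I=0.0, rundown_per_sweep=0.9, g_leak=0.0)
        rec = simulate_recording(slhv1, protocol, Solutions(), nr)
        sl = rec.epoch_slice(2)  # fixed reference step
        refs = rec.currents[:, sl][:, -5:].mean(axis=1)
        assert refs[1] / refs[0] == pytest.approx(0.9, rel=1e-6)
        assert refs[2] / refs[0] == pytest.approx(0.81, rel=1e-6)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, slhv1):
        protocol = standard_step_protocol(n_sweeps=2)
        a = simulate_recording(slhv1, protocol, Solutions(), NoiseRundown(seed=7))
        b = simulate_recording(slhv1, protocol, Solutions(), NoiseRundown(seed=7))
        assert np.array_equal(a.currents, b.currents)

    def test_different_seeds_differ(self, slhv1):
        protocol = standard_step_protocol(n_sweeps=1)
        a = simulate_recording(slhv1, protocol, Solutions(), NoiseRundown(seed=7))
        b = simulate_recording(slhv1, protocol, Solutions(), NoiseRundown(seed=8))
        assert not np.array_equal(a.currents, b.currents)


class TestSelectivityByConstruction:
    @pytest.mark.parametrize("dph", [-0.5, 0.0, 0.5, 1.0])
    def test_tail_currents_reverse_at_nernst(self, aohv1, dph):
        sol = Solutions(pH_i=6.0, pH_o=6.0 + dph)
        e_h = nernst_potential(sol.pH_i, sol.pH_o, sol.T)
        protocol = reversal_protocol(
            v_prepulse=60.0,
            v_tail_start=e_h - 20.0,
            sweep_increment=2.5,
            n_sweeps=17,
        )
        nr = NoiseRundown(sigma_I=0.0, rundown_per_sweep=1.0, g_leak=0.0)
        rec = simulate_recording(aohv1, protocol, sol, nr)
        iv = tail_iv(rec, 2)
        assert estimate_reversal(iv) == pytest.approx(e_h, abs=0.5)
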