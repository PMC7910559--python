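"""Gating-model unit tests: Nernst potential, pH coupling of V1/2,
equilibrium open probability, and blocker arithmetic."""

import numpy as np
import pytest
from scipy.linalg import null_space

from hvkit import (
    BlockerModel,
    ChannelModel,
    GatingScheme,
    Solutions,
    apply_blocker,
    effective_v_half,
    equilibrium_occupancies,
    nernst_potential,
    steady_state_po,
)
from hvkit.constants import thermal_voltage
from hvkit.model import transition_rates, two_state_scheme


class TestNernstPotential:
    @pytest.mark.parametrize(
        "ph_i, ph_o, expected",
        [
            (6.0, 6.0, 0.0),  # no gradient, no driving force
            (6.0, 7.0, -58.9),  # one pH unit: the printed reference constant
            (5.5, 6.5, -58.9),  # same gradient, different absolute pH
            (5.5, 7.5, -117.9),  # two pH units double the potential
            (7.0, 6.0, 58.9),  # inverted gradient flips the sign
        ],
    )
    def test_reference_values_at_297K(self, ph_i, ph_o, expected):
        assert nernst_potential(ph_i, ph_o, 297.0) == pytest.approx(
            expected, abs=0.05
        )

    def test_scales_linearly_with_temperature(self):
        assert nernst_potential(6.0, 7.0, 594.0) == pytest.approx(
            2 * nernst_potential(6.0, 7.0, 297.0)
        )

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            nernst_potential(6.0, 7.0, 0.0)


class TestEffectiveVHalf:
    def test_reference_condition_is_identity(self, slhv1):
        assert effective_v_half(slhv1, Solutions(6.0, 6.0)) == slhv1.v_half_ref

    def test_dpH_coupling_is_linear(self):
        m = ChannelModel(g_max=1.0, v_half_ref=0.0, s=8.0, c_dpH=-85.0)
        # DpH = +1 with pH_i perfused down one unit
        assert effective_v_half(m, Solutions(5.0, 6.0)) == pytest.approx(-85.0)

    def test_symmetric_ph_slope_matches_coupling(self, slhv1):
        lo = effective_v_half(slhv1, Solutions(5.5, 5.5))
        hi = effective_v_half(slhv1, Solutions(6.5, 6.5))
        assert hi - lo == pytest.approx(slhv1.c_sym * 1.0)


class TestSteadyStatePo:
    def test_half_activation_midpoint(self, slhv1):
        vh = effective_v_half(slhv1, Solutions())
        assert steady_state_po(vh, slhv1) == pytest.approx(0.5, abs=1e-9)

    def test_slhv1_at_reference_voltage(self, slhv1):
        # published worked example: G/Gmax at +50 mV
        assert steady_state_po(50.0, slhv1) == pytest.approx(0.613, abs=5e-4)

    def test_three_state_matches_kinetic_stationary_state(self, three_state_model):
        """Thermodynamic occupancy equals the null space of the rate matrix
        built independently from the transition rates."""
        sol = Solutions()
        for V in (-40.0, 0.0, 10.0, 35.0):
            occ = equilibrium_occupancies(V, three_state_model, sol)
            alpha, beta = transition_rates(V, three_state_model, sol)
            n = three_state_model.scheme.n_states
            Q = np.zeros((n, n))
            for j in range(n - 1):
                Q[j + 1, j] += alpha[j]
                Q[j, j] -= alpha[j]
                Q[j, j + 1] += beta[j]
                Q[j + 1, j + 1] -= beta[j]
            ns = null_space(Q)[:, 0]
            ns = ns / ns.sum()
            assert occ == pytest.approx(ns, abs=1e-12)
            assert steady_state_po(V, three_state_model, sol) == pytest.approx(
                ns[-1], abs=1e-12
            )

    def test_three_state_half_activation_constrained(self, three_state_model):
        vh = effective_v_half(three_state_model, Solutions())
        assert steady_state_po(vh, three_state_model) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_occupancies_sum_to_one(self, three_state_model):
        occ = equilibrium_occupancies(-20.0, three_state_model)
        assert occ.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_zero_slope(self):
        with pytest.raises(ValueError):
            ChannelModel(g_max=1.0, v_half_ref=0.0, s=0.0)


class TestTwoStateChargeIdentity:
    def test_slope_charge_coupling_at_297K(self):
        # s = 7.6 mV corresponds to 3.37 elementary charges at 297 K
        scheme = two_state_scheme(7.6)
        assert scheme.z_total == pytest.approx(3.37, abs=0.005)

    def test_identity_is_exact(self):
        for s in (5.0, 7.6, 11.6, 20.0):
            scheme = two_state_scheme(s)
            assert scheme.z_total * s == pytest.approx(
                thermal_voltage(297.0), rel=1e-12
            )


class TestApplyBlocker:
    def test_zero_concentration_is_identity(self, slhv1):
        blk = BlockerModel(mode="open-channel", conc=0.0, Kd=50.0)
        assert apply_blocker(slhv1, blk) is slhv1

    def test_open_channel_block_halves_conductance_at_kd(self, slhv1):
        blk = BlockerModel(mode="open-channel", conc=50.0, Kd=50.0)
        blocked = apply_blocker(slhv1, blk)
        assert blocked.g_max == pytest.approx(slhv1.g_max / 2)
        # kinetics untouched
        assert blocked.scheme == slhv1.scheme
        assert blocked.v_half_ref == slhv1.v_half_ref

    def test_closed_state_block_shifts_and_slows(self, slhv1):
        blk = BlockerModel(
            mode="closed-state", conc=100.0, Kd=100.0, dV_half=30.0, slow_factor=4.0
        )
        blocked = apply_blocker(slhv1, blk)
        # half occupancy at conc = Kd: half the saturating shift
        assert blocked.v_half_ref == pytest.approx(slhv1.v_half_ref + 15.0)
        assert blocked.g_max == slhv1.g_max
        for r_new, r_old in zip(blocked.scheme.rate0, slhv1.scheme.rate0):
            assert r_new == pytest.approx(r_old / 4.0)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            BlockerModel(mode="open-channel", conc=-1.0, Kd=10.0)

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError):
            BlockerModel(mode="allosteric", conc=1.0, Kd=10.0)


class TestInvariants:
    def test_solutions_validation(self):
        with pytest.raises(ValueError):
            Solutions(pH_i=0.0)
        with pytest.raises(ValueError):
            Solutions(T=-5.0)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            GatingScheme(z_step=(-1.0,), rate0=(1.0,))
        with pytest.raises(ValueError):
            GatingScheme(z_step=(1.0, 1.0), rate0=(1.0,))

    def test_deactivation_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ChannelModel(
                g_max=1.0,
                v_half_ref=0.0,
                s=8.0,
                deact_components=((0.5, 10.0), (0.2, 50.0)),
            )
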