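"""Parametric gating model for voltage-gated proton (Hv) channels.

The channel is described by a linear kinetic scheme C_{n-1} ... C_1 -> O with
one voltage-sensing transition per step.  Each transition j carries a gating
charge z_j (elementary charges); its equilibrium constant at voltage V is

    K_j(V) = exp(z_j * (V - V0) / (k_B T / e0)),

with a single offset V0 chosen so that the equilibrium open probability is 1/2
at the channel's half-activation voltage.  For a two-state scheme this reduces
exactly to the Boltzmann function 1/(1 + exp((V1/2 - V)/s)) with
s = k_B T / (e0 z), which ties the Boltzmann slope to the gating charge.

Voltage dependence of the half-activation point on the proton gradient is
phenomenological: V1/2 shifts linearly with the transmembrane pH gradient
(DpH = pH_o - pH_i) and, independently, with symmetric pH changes at DpH = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import T_REF, nernst_slope, thermal_voltage

__all__ = [
    "Solutions",
    "GatingScheme",
    "ChannelModel",
    "BlockerModel",
    "nernst_potential",
    "effective_v_half",
    "steady_state_po",
    "equilibrium_occupancies",
    "apply_blocker",
]

REF_PH = 6.0  # reference condition: pH_i = pH_o = 6.0


@dataclass(frozen=True)
class Solutions:
    """Recording solutions: intra/extracellular pH and temperature."""

    pH_i: float = 6.0
    pH_o: float = 6.0
    T: float = T_REF

    def __post_init__(self) -> None:
        if not (0.0 < self.pH_i < 14.0 and 0.0 < self.pH_o < 14.0):
            raise ValueError("pH values must lie in (0, 14)")
        if self.T <= 0:
            raise ValueError("absolute temperature must be positive")

    @property
    def dpH(self) -> float:
        """Transmembrane pH gradient, pH_o - pH_i."""
        return self.pH_o - self.pH_i


@dataclass(frozen=True)
class GatingScheme:
    """Linear scheme C_{n-1} ... C_1 -> O.

    z_step[j] is the gating charge of transition j (deepest closed state
    first); rate0[j] is the shared forward/backward rate prefactor in 1/ms,
    i.e. alpha_j(V) = rate0_j exp(+z_j (V-V0)/2Vt), beta_j with the opposite
    sign, so K_j = alpha/beta has no kinetic free parameter.
    """

    z_step: tuple[float, ...]
    rate0: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_step", tuple(float(z) for z in self.z_step))
        object.__setattr__(self, "rate0", tuple(float(r) for r in self.rate0))
        if len(self.z_step) < 1:
            raise ValueError("scheme needs at least one transition (two states)")
        if len(self.rate0) != len(self.z_step):
            raise ValueError("rate0 and z_step must have one entry per transition")
        if any(z < 0 for z in self.z_step):
            raise ValueError("per-transition gating charges must be >= 0")
        if any(r <= 0 for r in self.rate0):
            raise ValueError("rate prefactors must be positive")

    @property
    def n_states(self) -> int:
        return len(self.z_step) + 1

    @property
    def z_total(self) -> float:
        """Total gating charge; what the limiting-slope method estimates."""
        return sum(self.z_step)


def two_state_scheme(s: float, rate0: float = 1.0, T: float = T_REF) -> GatingScheme:
    """Two-state scheme whose charge matches Boltzmann slope ``s`` at ``T``."""
    if s == 0:
        raise ValueError("slope parameter s must be nonzero")
    return GatingScheme(z_step=(thermal_voltage(T) / abs(s),), rate0=(rate0,))


@dataclass(frozen=True)
class ChannelModel:
    """Generative truth for one channel variant.

    Parameters
    ----------
    g_max : maximal conductance, nS
    v_half_ref : half-activation voltage at pH_i = pH_o = 6.0, mV
    s : Boltzmann slope factor, mV (positive: opens on depolarization)
    c_dpH : V1/2 shift per unit DpH, mV/pH (negative: raising pH_o
        left-shifts activation, the animal-Hv direction)
    c_sym : V1/2 shift per unit symmetric pH change at DpH = 0, mV/pH
    scheme : kinetic scheme; defaults to the two-state scheme tied to ``s``
    m_act : nominal number of rate-limiting closed transitions (metadata;
        the simulated lag comes from the scheme itself)
    deact_components : nominal (fraction, tau_ms) tail mixture the preset is
        tuned to produce; purely descriptive for multi-state schemes
    """

    g_max: float
    v_half_ref: float
    s: float
    c_dpH: float = 0.0
    c_sym: float = 0.0
    scheme: GatingScheme | None = None
    m_act: int = 1
    deact_components: tuple[tuple[float, float], ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.s == 0:
            raise ValueError("slope parameter s must be nonzero")
        if self.scheme is None:
            object.__setattr__(self, "scheme", two_state_scheme(self.s))
        if self.deact_components:
            total = sum(f for f, _ in self.deact_components)
            if abs(total - 1.0) > 1e-6:
                raise ValueError("deact_components fractions must sum to 1")


@dataclass(frozen=True)
class BlockerModel:
    """Inhibitor acting either on the open or on the closed state.

    Open-channel blockers (2GBI/ClGBI-like) plug the conducting state: they
    scale the maximal conductance by 1/(1 + conc/Kd) and leave activation
    kinetics untouched.  Closed-state stabilizers (Zn2+-like) make opening
    harder: they shift V1/2 toward depolarized values by
    dV_half * conc/(conc + Kd) and slow activation by ``slow_factor``.
    """

    mode: str  # "open-channel" | "closed-state"
    conc: float  # uM
    Kd: float  # uM
    dV_half: float = 0.0  # mV at saturating block (closed-state mode)
    slow_factor: float = 1.0  # tau_on multiplier at this conc (closed-state)

    def __post_init__(self) -> None:
        if self.mode not in ("open-channel", "closed-state"):
            raise ValueError(f"unknown blocker mode {self.mode!r}")
        if self.conc < 0:
            raise ValueError("blocker concentration must be >= 0")
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if self.slow_factor <= 0:
            raise ValueError("slow_factor must be positive")

    @property
    def occupancy(self) -> float:
        """Fractional receptor occupancy conc/(conc + Kd)."""
        return self.conc / (self.conc + self.Kd)


def nernst_potential(pH_i: float, pH_o: float, T: float = T_REF) -> float:
    """Proton Nernst potential E_H = -ln(10)(RT/F)(pH_o - pH_i), in mV.

    At 297 K this is the -58.9 mV per pH-unit reference line used to judge
    perfect proton selectivity.
    """
    sol = Solutions(pH_i=pH_i, pH_o=pH_o, T=T)
    return -nernst_slope(T) * sol.dpH


def effective_v_half(model: ChannelModel, solutions: Solutions) -> float:
    """Half-activation voltage under the given solutions, mV.

    V1/2 = v_half_ref + c_sym*(pH_i - 6) + c_dpH*DpH, with both couplings
    linear and independent (a phenomenological description of the measured
    DpH and symmetric-pH dependences).
    """
    return (
        model.v_half_ref
        + model.c_sym * (solutions.pH_i - REF_PH)
        + model.c_dpH * solutions.dpH
    )


def _v0_for_half_activation(scheme: GatingScheme, v_half: float, vt: float) -> float:
    """Offset V0 such that the scheme's equilibrium P_O(v_half) = 1/2."""
    if scheme.n_states == 2:
        return v_half
    z = np.asarray(scheme.z_step)

    def po_minus_half(v0: float) -> float:
        return _po_from_v0(z, v_half, v0, vt) - 0.5

    # P_O is monotone decreasing in V0; bracket generously.
    span = 50.0 * vt / max(z.sum(), 1e-9) + 500.0
    return brentq(po_minus_half, v_half - span, v_half + span, xtol=1e-10)


def _po_from_v0(z: np.ndarray, V: float, v0: float, vt: float) -> float:
    logK = z * (V - v0) / vt
    # cumulative log partial products, state occupancies ~ [1, K1, K1K2, ...]
    logw = np.concatenate(([0.0], np.cumsum(logK)))
    logw -= logw.max()  # overflow guard
    w = np.exp(logw)
    return float(w[-1] / w.sum())


def equilibrium_occupancies(
    V: float, model: ChannelModel, solutions: Solutions | None = None
) -> np.ndarray:
    """Equilibrium occupancy of every state at voltage ``V`` (sums to 1).

    Order: deepest closed state first, open state last.
    """
    solutions = solutions or Solutions()
    vt = thermal_voltage(solutions.T)
    v_half = effective_v_half(model, solutions)
    v0 = _v0_for_half_activation(model.scheme, v_half, vt)
    z = np.asarray(model.scheme.z_step)
    logK = z * (V - v0) / vt
    logw = np.concatenate(([0.0], np.cumsum(logK)))
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def steady_state_po(
    V: float | np.ndarray, model: ChannelModel, solutions: Solutions | None = None
) -> float | np.ndarray:
    """Equilibrium open probability at voltage ``V`` (mV).

    Two-state schemes give exactly 1/(1 + exp((V1/2 - V)/s)); longer linear
    schemes give the open-state occupancy of the scheme's equilibrium,
    constrained so P_O = 1/2 at the effective half-activation voltage.
    """
    solutions = solutions or Solutions()
    vt = thermal_voltage(solutions.T)
    v_half = effective_v_half(model, solutions)
    v0 = _v0_for_half_activation(model.scheme, v_half, vt)
    z = np.asarray(model.scheme.z_step)
    V_arr = np.asarray(V, dtype=float)
    out = np.empty(V_arr.size)
    for i, v in enumerate(V_arr.ravel()):
        out[i] = _po_from_v0(z, float(v), v0, vt)
    return float(out[0]) if V_arr.ndim == 0 else out.reshape(V_arr.shape)


def transition_rates(
    V: float, model: ChannelModel, solutions: Solutions | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward (alpha) and backward (beta) rates per transition at ``V``, 1/ms.

    Charge is split symmetrically across the barrier, so
    alpha_j/beta_j = K_j(V) and the relaxation speed is set by rate0 alone.
    """
    solutions = solutions or Solutions()
    vt = thermal_voltage(solutions.T)
    v_half = effective_v_half(model, solutions)
    v0 = _v0_for_half_activation(model.scheme, v_half, vt)
    z = np.asarray(model.scheme.z_step)
    r0 = np.asarray(model.scheme.rate0)
    x = z * (V - v0) / (2.0 * vt)
    # clip to keep rates finite at extreme voltages
    x = np.clip(x, -30.0, 30.0)
    return r0 * np.exp(x), r0 * np.exp(-x)


def apply_blocker(model: ChannelModel, blocker: BlockerModel) -> ChannelModel:
    """Return a copy of ``model`` modified by the blocker at its concentration.

    Open-channel mode divides g_max by (1 + conc/Kd) and leaves the gating
    scheme untouched.  Closed-state mode leaves g_max untouched, shifts
    v_half_ref depolarized by dV_half * occupancy, and divides every rate
    prefactor by slow_factor (tau_on is multiplied by slow_factor; the
    equilibrium curve keeps its shape apart from the shift).
    """
    if blocker.conc == 0:
        return model
    if blocker.mode == "open-channel":
        return replace(model, g_max=model.g_max / (1.0 + blocker.conc / blocker.Kd))
    shifted = model.v_half_ref + blocker.dV_half * blocker.occupancy
    slowed = GatingScheme(
        z_step=model.scheme.z_step,
        rate0=tuple(r / blocker.slow_factor for r in model.scheme.rate0),
    )
    return replace(model, v_half_ref=shifted, scheme=slowed)
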