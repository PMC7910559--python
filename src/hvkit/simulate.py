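"""Synthetic voltage-clamp recordings from the parametric gating model.

Channel state probabilities follow the linear scheme's master equation,
integrated with the matrix exponential over each constant-voltage sampling
interval and with sub-millisecond piecewise-constant steps along ramps.
The recorded current at each sample is

    I = g_leak (V - E_leak) + r^sweep g_max P_O (V - E_H) + noise,

with geometric per-sweep rundown r, ohmic leak, perfect proton selectivity
(the channel-mediated current reverses at the Nernst potential E_H), and
Gaussian sampling noise.  Everything stochastic is driven by one integer
seed, so identical seeds give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import ProtocolError
from .model import (
    ChannelModel,
    Solutions,
    equilibrium_occupancies,
    nernst_potential,
    transition_rates,
)
from .protocol import VoltageProtocol
from .trace_io import Recording

__all__ = [
    "NoiseRundown",
    "simulate_recording",
    "open_probability_course",
    "state_probability_course",
]

MAX_SUBSTEP_MS = 1.0  # ramp integration sub-step


@dataclass(frozen=True)
class NoiseRundown:
    """Recording artifacts: sampling noise, rundown, and ohmic leak."""

    sigma_I: float = 2.0  # pA
    rundown_per_sweep: float = 0.98  # conductance retention per sweep
    g_leak: float = 0.2  # nS
    E_leak: float = 0.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_I < 0:
            raise ValueError("sigma_I must be >= 0")
        if not (0.0 < self.rundown_per_sweep <= 1.0):
            raise ValueError("rundown_per_sweep must be in (0, 1]")
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")


def _generator(V: float, model: ChannelModel, solutions: Solutions) -> np.ndarray:
    """Master-equation generator Q (dP/dt = Q P) at voltage ``V``."""
    alpha, beta = transition_rates(V, model, solutions)
    n = model.scheme.n_states
    Q = np.zeros((n, n))
    for j in range(n - 1):
        Q[j + 1, j] += alpha[j]
        Q[j, j] -= alpha[j]
        Q[j, j + 1] += beta[j]
        Q[j + 1, j + 1] -= beta[j]
    return Q


def open_probability_course(
    model: ChannelModel,
    protocol: VoltageProtocol,
    solutions: Solutions | None = None,
    sweep: int = 0,
) -> np.ndarray:
    """Open-state probability at every sample of one sweep (no noise).

    The initial condition is the gating equilibrium at the first epoch's
    starting voltage.  Occupancies are propagated exactly (matrix
    exponential) over each sampling interval; ramp intervals are split into
    piecewise-constant sub-steps no longer than 1 ms evaluated at the
    sub-step midpoint voltage.
    """
    return state_probability_course(model, protocol, solutions, sweep)[:, -1]


def state_probability_course(
    model: ChannelModel,
    protocol: VoltageProtocol,
    solutions: Solutions | None = None,
    sweep: int = 0,
) -> np.ndarray:
    """State-probability matrix (n_samples, n_states) along one sweep."""
    solutions = solutions or Solutions()
    dt = protocol.dt
    two_state = model.scheme.n_states == 2
    v00, _ = protocol.epoch_voltage(0, sweep)
    P = equilibrium_occupancies(v00, model, solutions)
    out = np.empty((protocol.n_samples, model.scheme.n_states))
    k = 0
    for idx, ep in enumerate(protocol.segments):
        n = protocol.epoch_samples(idx)
        v0, v1 = protocol.epoch_voltage(idx, sweep)
        if ep.kind in ("hold", "step"):
            if two_state:
                alpha, beta = transition_rates(v0, model, solutions)
                lam = float(alpha[0] + beta[0])
                p_inf = float(alpha[0] / lam)
                decay = np.exp(-lam * dt)
                po = P[1]
                for _ in range(n):
                    out[k] = (1.0 - po, po)
                    k += 1
                    po = p_inf + (po - p_inf) * decay
                P = np.array([1.0 - po, po])
            else:
                prop = expm(_generator(v0, model, solutions) * dt)
                for _ in range(n):
                    out[k] = P
                    k += 1
                    P = prop @ P
        else:  # ramp
            m = max(1, int(np.ceil(dt / MAX_SUBSTEP_MS)))
            h = dt / m
            for i in range(n):
                out[k] = P
                k += 1
                for j in range(m):
                    frac = (i + (j + 0.5) / m) / n
                    v = v0 + (v1 - v0) * frac
                    if two_state:
                        alpha, beta = transition_rates(v, model, solutions)
                        lam = float(alpha[0] + beta[0])
                        p_inf = float(alpha[0] / lam)
                        po = p_inf + (P[1] - p_inf) * np.exp(-lam * h)
                        P = np.array([1.0 - po, po])
                    else:
                        P = expm(_generator(v, model, solutions) * h) @ P
        # renormalize against accumulated round-off
        P = np.clip(P, 0.0, None)
        P /= P.sum()
    return out


def simulate_recording(
    model: ChannelModel,
    protocol: VoltageProtocol,
    solutions: Solutions | None = None,
    noise_rundown: NoiseRundown | None = None,
) -> Recording:
    """Generate an episodic recording from the gating model.

    Returns a :class:`~hvkit.trace_io.Recording` whose command waveform and
    metadata reflect the protocol and solutions used.
    """
    solutions = solutions or Solutions()
    nr = noise_rundown or NoiseRundown()
    if not np.isfinite([m for m in model.scheme.rate0]).all():
        raise ProtocolError("non-finite rate prefactors")
    rng = np.random.default_rng(nr.seed)
    e_h = nernst_potential(solutions.pH_i, solutions.pH_o, solutions.T)

    currents = np.empty((protocol.n_sweeps, protocol.n_samples))
    voltages = np.empty_like(currents)
    for s in range(protocol.n_sweeps):
        v = protocol.sweep_waveform(s)
        if model.g_max > 0:
            po = state_probability_course(model, protocol, solutions, s)[:, -1]
        else:
            po = np.zeros(protocol.n_samples)
        g_eff = model.g_max * nr.rundown_per_sweep**s
        i_chan = g_eff * po * (v - e_h)
        i_leak = nr.g_leak * (v - nr.E_leak)
        noise = nr.sigma_I * rng.standard_normal(protocol.n_samples)
        currents[s] = i_leak + i_chan + noise
        voltages[s] = v
    return Recording(
        dt=protocol.dt,
        currents=currents,
        voltages=voltages,
        solutions=solutions,
        protocol=protocol,
        label=model.label,
        seed=nr.seed,
    )
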