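"""Reusable study recipes built from the pipeline primitives.

Each function reproduces one complete measurement the way it is done at the
rig: generate (or accept) data, run the relevant pipeline stages, and
return the derived quantity.  They are the building blocks of the examples
and of the package's self-validation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import linregress

from .constants import T_REF
from .model import Solutions, effective_v_half, nernst_potential
from .pipeline import (
    BoltzmannFit,
    GVCurve,
    ZgEstimate,
    correct_rundown,
    derive_gv,
    eval_boltzmann,
    fit_boltzmann,
    limiting_slope_zg,
    steady_iv,
    subtract_leak,
)
from .presets import load_preset, preset_parameters
from .protocol import LEAK_EPOCHS, REFERENCE_EPOCH, TEST_EPOCH, ramp_protocol, standard_step_protocol
from .simulate import NoiseRundown, simulate_recording

__all__ = [
    "synthetic_gv_fits",
    "mean_v_half",
    "boltzmann_recovery",
    "chimera_shift",
    "symmetric_ph_slope",
    "limiting_slope_from_ramp",
    "fit_gv_from_recording",
]


def synthetic_gv_fits(
    v_half: float,
    s: float,
    voltages: np.ndarray,
    n_replicates: int = 5,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> list[BoltzmannFit]:
    """Boltzmann fits of seeded noisy normalized G-V replicates.

    Each replicate samples the Boltzmann curve at ``voltages`` and adds
    Gaussian noise of standard deviation ``noise_sd`` to the normalized
    conductance (replicate k uses seed ``seed + k``).
    """
    voltages = np.asarray(voltages, dtype=float)
    fits = []
    for k in range(n_replicates):
        rng = np.random.default_rng(seed + k)
        y = eval_boltzmann(voltages, v_half, s) + noise_sd * rng.standard_normal(
            voltages.size
        )
        gv = GVCurve(
            voltages=voltages,
            g=y,
            g_norm=y,
            v_rev=float("nan"),
        )
        fits.append(fit_boltzmann(gv))
    return fits


def mean_v_half(fits: list[BoltzmannFit]) -> tuple[float, float]:
    """Mean and SEM of the fitted half-activation voltages."""
    v = np.array([f.v_half for f in fits])
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), sem


def boltzmann_recovery(
    preset: str,
    voltages: np.ndarray,
    n_replicates: int = 5,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean ± SEM of fitted V1/2 from noisy synthetic G-V replicates
    generated with a preset's published Boltzmann parameters."""
    p = preset_parameters(preset)
    fits = synthetic_gv_fits(
        p["v_half_mV"], p["slope_mV"], voltages, n_replicates, noise_sd, seed
    )
    return mean_v_half(fits)


def chimera_shift(
    preset_a: str,
    preset_b: str,
    n_replicates: int = 5,
    noise_sd: float = 0.03,
    seed: int = 0,
    span: float = 60.0,
    step: float = 10.0,
) -> float:
    """Difference of mean fitted V1/2 between two presets (a minus b), mV.

    Replicate G-V data are generated around each preset's own half-activation
    voltage (V1/2 ± span, sampled every ``step`` mV) so both rising phases
    are equally well covered.
    """
    means = []
    for i, name in enumerate((preset_a, preset_b)):
        p = preset_parameters(name)
        v = np.arange(p["v_half_mV"] - span, p["v_half_mV"] + span + step / 2, step)
        m, _ = boltzmann_recovery(name, v, n_replicates, noise_sd, seed + 100 * i)
        means.append(m)
    return means[0] - means[1]


def fit_gv_from_recording(recording) -> BoltzmannFit:
    """Leak-subtract, rundown-correct, and Boltzmann-fit one recording.

    Assumes the standard step protocol layout (leak epochs 0-1, reference
    epoch 2, test epoch 4) and uses V_rev = E_H, as appropriate for a
    strongly proton-selective channel.
    """
    rec, _ = subtract_leak(recording, list(LEAK_EPOCHS))
    rec, _ = correct_rundown(rec, REFERENCE_EPOCH, noise_floor=0.5)
    sol = rec.solutions
    v_rev = nernst_potential(sol.pH_i, sol.pH_o, sol.T)
    gv = derive_gv(steady_iv(rec, TEST_EPOCH), v_rev)
    return fit_boltzmann(gv)


def symmetric_ph_slope(
    preset: str = "SlHv1",
    phs: tuple[float, ...] = (5.5, 6.0, 6.5),
    n_replicates: int = 5,
    seed: int = 0,
    n_sweeps: int = 13,
) -> tuple[float, dict[float, float]]:
    """Slope of V1/2 against pH under symmetric conditions (DpH = 0), mV/pH.

    For every pH, ``n_replicates`` full recordings are simulated with the
    standard step protocol (test voltages centered on the condition's
    half-activation point), pushed through leak subtraction, rundown
    correction, G-V derivation, and Boltzmann fitting; the slope is the OLS
    fit of the per-pH mean V1/2 against pH.
    """
    model = load_preset(preset)
    means: dict[float, float] = {}
    for j, ph in enumerate(phs):
        solutions = Solutions(pH_i=ph, pH_o=ph)
        v_half = effective_v_half(model, solutions)
        protocol = standard_step_protocol(
            v_test_start=round(v_half - 60.0),
            n_sweeps=n_sweeps,
            sweep_increment=round(120.0 / (n_sweeps - 1)),
            v_ref=round(v_half + 30.0),
            test_duration=1500.0,
        )
        vals = []
        for k in range(n_replicates):
            nr = NoiseRundown(seed=seed + 97 * j + k)
            rec = simulate_recording(model, protocol, solutions, nr)
            vals.append(fit_gv_from_recording(rec).v_half)
        means[ph] = float(np.mean(vals))
    res = linregress(list(means.keys()), list(means.values()))
    return float(res.slope), means


def limiting_slope_from_ramp(
    preset: str = "SlHv1-seq",
    pH_i: float = 5.5,
    pH_o: float = 6.0,
    v_start: float = -80.0,
    v_end: float = -20.0,
    ramp_duration_ms: float = 20_000.0,
    v_prepulse: float = 30.0,
    po_max: float = 0.01,
    po_min: float = 1e-3,
    sigma_I: float = 0.5,
    seed: int = 0,
    dt: float = 2.0,
    bin_mV: float = 1.0,
) -> ZgEstimate:
    """Gating charge by the limiting-slope method on a simulated slow ramp.

    A pre-pulse drives the channel to maximal conductance (measuring
    G_max); the slow ramp then samples the low-open-probability limb.  The
    ramp current is leak-subtracted, averaged in ``bin_mV``-wide voltage
    bins (averaging before the logarithm avoids the positivity bias that
    raw noisy samples would introduce at very low P_o), converted to open
    probability P_o = G/G_max with G = I/(V - E_H), and z_g comes from the
    OLS slope of ln(P_o) vs V on the window po_min <= P_o <= po_max (the
    lower bound keeps bins with adequate signal-to-noise in the fit).
    """
    model = load_preset(preset)
    solutions = Solutions(pH_i=pH_i, pH_o=pH_o)
    protocol = ramp_protocol(
        v_start=v_start,
        v_end=v_end,
        ramp_duration=ramp_duration_ms,
        v_prepulse=v_prepulse,
        dt=dt,
    )
    nr = NoiseRundown(sigma_I=sigma_I, rundown_per_sweep=1.0, g_leak=0.1, seed=seed)
    rec = simulate_recording(model, protocol, solutions, nr)
    e_h = nernst_potential(pH_i, pH_o, solutions.T)

    # leak from the low-voltage end of the ramp (channels closed there)
    ramp_epoch = len(protocol.segments) - 1
    sl = rec.epoch_slice(ramp_epoch)
    v_ramp = rec.voltages[0, sl]
    i_ramp = rec.currents[0, sl]
    closed = v_ramp <= v_start + 0.25 * (v_end - v_start)
    g_leak, i0 = np.polyfit(v_ramp[closed], i_ramp[closed], 1)
    i_chan = i_ramp - (g_leak * v_ramp + i0)

    # G_max from the isochronal current at the end of the pre-pulse
    pre_sl = rec.epoch_slice(1)
    i_pre = float(np.mean(rec.currents[0, pre_sl][-5:]))
    i_pre -= g_leak * v_prepulse + i0
    g_max = i_pre / (v_prepulse - e_h)

    # voltage binning: average current within each bin before the log
    edges = np.arange(v_start, v_end + bin_mV / 2, bin_mV)
    which = np.digitize(v_ramp, edges)
    v_bin, i_bin = [], []
    for b in range(1, edges.size):
        in_bin = which == b
        if np.any(in_bin):
            v_bin.append(v_ramp[in_bin].mean())
            i_bin.append(i_chan[in_bin].mean())
    v_bin = np.asarray(v_bin)
    i_bin = np.asarray(i_bin)

    po = i_bin / (v_bin - e_h) / g_max
    keep = po >= po_min
    return limiting_slope_zg(po[keep], v_bin[keep], po_max=po_max, T=solutions.T)
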