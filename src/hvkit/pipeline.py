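"""Patch-clamp measurement pipeline for Hv-channel recordings.

Implements the standard analysis chain for voltage-gated proton currents:
ohmic leak subtraction, rundown correction against a reference pulse,
single-exponential activation fits with lag exclusion, conductance-voltage
(G-V) construction G = I/(V - V_rev) and Boltzmann fitting, reversal
potential and proton-selectivity analysis, limiting-slope gating-charge
estimation z_g = (k_B T / e0) * d ln(P_o)/dV, and inhibition/kinetics
quantification for pharmacology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .constants import nernst_slope, thermal_voltage
from .errors import FitError, NoRiseError
from .model import Solutions
from .trace_io import Recording

__all__ = [
    "IVCurve",
    "GVCurve",
    "BoltzmannFit",
    "ExpFit",
    "TailMetrics",
    "ZgEstimate",
    "SelectivityFit",
    "DpHShiftResult",
    "LeakFit",
    "subtract_leak",
    "correct_rundown",
    "fit_activation",
    "isochronal_current",
    "steady_iv",
    "derive_gv",
    "fit_boltzmann",
    "eval_boltzmann",
    "estimate_reversal",
    "selectivity_fit",
    "dpH_shift_analysis",
    "half_deactivation_time",
    "limiting_slope_zg",
    "inhibition_fraction",
    "tau_ratio",
]

#: first milliseconds after a voltage change excluded from fits
#: (capacitive-transient blanking)
BLANK_MS = 0.5


# ---------------------------------------------------------------------------
# result containers


@dataclass
class IVCurve:
    """Current-voltage relation. ``kind``: steady | instantaneous-tail | ramp."""

    voltages: np.ndarray  # mV
    currents: np.ndarray  # pA
    kind: str = "steady"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must have equal length")
        if self.kind not in ("steady", "instantaneous-tail", "ramp"):
            raise ValueError(f"unknown IV kind {self.kind!r}")
        if self.kind == "ramp" and np.any(np.diff(self.voltages) == 0):
            raise ValueError("ramp IV voltages must be strictly ordered")


@dataclass
class GVCurve:
    """Conductance-voltage relation with normalization bookkeeping."""

    voltages: np.ndarray  # mV, kept points only
    g: np.ndarray  # nS
    g_norm: np.ndarray  # G/G_max
    v_rev: float  # mV used in G = I/(V - V_rev)
    excluded_voltages: np.ndarray = field(default_factory=lambda: np.empty(0))
    kind: str = "steady"


@dataclass
class BoltzmannFit:
    """G/G_max = 1/(1 + exp((V1/2 - V)/s)) fit result."""

    v_half: float  # mV
    s: float  # mV, positive for activation by depolarization
    g_max: float
    v_half_err: float = float("nan")
    s_err: float = float("nan")
    g_max_err: float = float("nan")
    residual_norm: float = float("nan")


@dataclass
class ExpFit:
    """Single-exponential activation fit I = a exp(-(t-t0)/tau_on) + c."""

    a: float  # pA
    tau_on: float  # ms
    c: float  # pA
    t0: float  # ms, start of the fitted window (post-lag)


@dataclass
class TailMetrics:
    """Instantaneous tail amplitude and half-deactivation time."""

    I_o: float  # pA at repolarization onset
    t_half: float  # ms
    sub_sample: bool = False  # decay completed within one sampling interval


@dataclass
class ZgEstimate:
    """Limiting-slope gating charge with the ln(P_o) fit behind it."""

    z_g: float  # elementary charges
    slope: float  # d ln(P_o)/dV, 1/mV
    intercept: float
    po_max: float
    n_points: int
    T: float


@dataclass
class SelectivityFit:
    """OLS fit of reversal potential against the pH gradient."""

    slope: float  # mV per DpH unit
    intercept: float  # mV
    mean_vrev: dict[float, float]
    nernst_slope: float  # the perfect-selectivity reference, mV per pH
    deviation: float  # slope - (-nernst_slope)


@dataclass
class DpHShiftResult:
    """V1/2 shifts per unit change in DpH and activation thresholds."""

    shift_per_dpH: dict[tuple[float, float], float]  # (dpH_a, dpH_b) -> mV/pH
    v_threshold: dict[float, float]  # dpH -> mV
    expected_animal_shift: dict[tuple[float, float], float]  # -40 mV/pH rule
    mean_shift_per_dpH: float


@dataclass
class LeakFit:
    """Per-sweep ohmic leak parameters."""

    g: np.ndarray  # nS per sweep
    E: np.ndarray  # mV per sweep
    biased: bool = False  # subthreshold window overlapped activated epochs


# ---------------------------------------------------------------------------
# preprocessing


def _window_samples(
    recording: Recording, window: "list[int] | tuple[float, float]"
) -> np.ndarray:
    """Sample indices for a window given as epoch indices or (t0, t1) in ms."""
    if isinstance(window, tuple) and len(window) == 2 and not isinstance(
        window[0], int
    ):
        t = recording.times()
        idx = np.where((t >= window[0]) & (t < window[1]))[0]
    else:
        idx = np.concatenate(
            [np.arange(*recording.protocol.epoch_bounds(e)) for e in window]
        )
    return idx


def subtract_leak(
    recording: Recording,
    subthreshold_window: "list[int] | tuple[float, float]",
    v_max_closed: float | None = None,
) -> tuple[Recording, LeakFit]:
    """Fit and subtract an ohmic leak g*(V - E) per sweep.

    The leak is identified from the designated subthreshold samples (epoch
    indices, or a (t_start_ms, t_end_ms) window), which must span at least
    two distinct voltages.  If ``v_max_closed`` is given and any designated
    sample is more depolarized, the window likely overlaps an activated
    epoch: a warning is emitted and the fit flagged as biased.
    """
    idx = _window_samples(recording, subthreshold_window)
    if idx.size == 0:
        raise ValueError("no subthreshold samples designated")
    biased = False
    if v_max_closed is not None and np.any(recording.voltages[:, idx] > v_max_closed):
        warnings.warn(
            "subthreshold window overlaps samples above v_max_closed; "
            "leak fit may be biased by channel current",
            stacklevel=2,
        )
        biased = True
    g = np.empty(recording.n_sweeps)
    E = np.empty(recording.n_sweeps)
    corrected = recording.currents.copy()
    for s in range(recording.n_sweeps):
        v = recording.voltages[s, idx]
        i = recording.currents[s, idx]
        if np.ptp(v) == 0:
            raise ValueError(
                "subthreshold window must span at least two distinct voltages"
            )
        slope, intercept = np.polyfit(v, i, 1)
        g[s] = slope
        E[s] = -intercept / slope if slope != 0 else 0.0
        corrected[s] -= slope * recording.voltages[s] + intercept
    out = Recording(
        dt=recording.dt,
        currents=corrected,
        voltages=recording.voltages.copy(),
        solutions=recording.solutions,
        protocol=recording.protocol,
        label=recording.label,
        seed=recording.seed,
    )
    return out, LeakFit(g=g, E=E, biased=biased)


def isochronal_current(
    trace: np.ndarray, dt: float, window_ms: float = 5.0
) -> float:
    """Mean current over the final ``window_ms`` of an epoch trace."""
    n = int(round(window_ms / dt))
    if n < 1 or n > trace.size:
        raise ValueError(
            f"isochronal window of {window_ms} ms does not fit in an epoch of "
            f"{trace.size * dt} ms"
        )
    return float(np.mean(trace[-n:]))


def correct_rundown(
    recording: Recording,
    reference_epoch: int,
    window_ms: float = 5.0,
    noise_floor: float = 0.0,
) -> tuple[Recording, np.ndarray]:
    """Rescale every sweep by its reference-pulse isochronal current.

    The reference depolarization precedes the test pulse in the protocol;
    sweep k is multiplied by I_ref(sweep 0)/I_ref(sweep k) so that a
    monotonic conductance loss across sweeps (rundown) cancels.  Returns the
    corrected recording and the scale factors applied.
    """
    sl = recording.epoch_slice(reference_epoch)
    refs = np.array(
        [
            isochronal_current(recording.currents[s, sl], recording.dt, window_ms)
            for s in range(recording.n_sweeps)
        ]
    )
    if np.any(np.abs(refs) <= noise_floor):
        raise ValueError(
            "reference isochronal current indistinguishable from zero"
        )
    scale = refs[0] / refs
    corrected = recording.currents * scale[:, None]
    out = Recording(
        dt=recording.dt,
        currents=corrected,
        voltages=recording.voltages.copy(),
        solutions=recording.solutions,
        protocol=recording.protocol,
        label=recording.label,
        seed=recording.seed,
    )
    return out, scale


# ---------------------------------------------------------------------------
# kinetic fits


def fit_activation(
    trace: np.ndarray,
    dt: float,
    lag_fraction: float = 0.1,
    min_rise: float = 0.0,
    blank_ms: float = BLANK_MS,
) -> ExpFit:
    """Fit a single exponential to an activating current, excluding the lag.

    The initial sigmoidal lag (much shorter than tau_on) is excluded by
    starting the fit where the current first crosses ``lag_fraction`` of its
    steady rise; I(t) = a exp(-(t - t0)/tau_on) + c is then fitted by least
    squares on [t0, end].
    """
    t = np.arange(trace.size) * dt
    blank = int(round(blank_ms / dt))
    tr = trace[blank:]
    tt = t[blank:]
    if tr.size < 5:
        raise FitError("trace too short to fit after blanking")
    i0 = tr[0]
    i_ss = float(np.mean(tr[-max(1, tr.size // 10):]))
    rise = i_ss - i0
    if abs(rise) <= min_rise:
        raise NoRiseError("no rise detected in activation trace")
    target = i0 + lag_fraction * rise
    sign = np.sign(rise)
    crossed = np.where(sign * (tr - target) >= 0)[0]
    if crossed.size == 0:
        raise NoRiseError("current never crosses the lag-exclusion threshold")
    k0 = crossed[0]
    t0 = tt[k0]
    y = tr[k0:]
    x = tt[k0:] - t0
    p0 = (y[0] - i_ss, max((x[-1] - x[0]) / 3.0, dt), i_ss)

    def model(tx, a, tau, c):
        return a * np.exp(-tx / tau) + c

    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0, bounds=([-np.inf, dt / 10, -np.inf], np.inf),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitError(f"activation fit did not converge: {exc}") from exc
    a, tau, c = popt
    return ExpFit(a=float(a), tau_on=float(tau), c=float(c), t0=float(t0))


def half_deactivation_time(
    tail_trace: np.ndarray, dt: float, blank_ms: float = BLANK_MS
) -> TailMetrics:
    """Time for a tail current to decay to half its instantaneous value.

    I_o is the current at the start of the repolarization (after the
    capacitive blanking window); t_half is the first crossing of I_o/2,
    linearly interpolated between samples and measured from the I_o sample.
    """
    blank = int(round(blank_ms / dt))
    tr = np.asarray(tail_trace, dtype=float)[blank:]
    if tr.size < 2:
        raise ValueError("tail trace too short after blanking")
    i_o = float(tr[0])
    if i_o == 0:
        raise ValueError("instantaneous tail current is zero")
    mag = np.abs(tr)  # decay toward zero from either sign
    half = abs(i_o) / 2.0
    below = np.where(mag <= half)[0]
    if below.size == 0:
        raise ValueError("tail current never decays to half its initial value")
    k = below[0]
    if k == 0:
        return TailMetrics(I_o=i_o, t_half=0.0, sub_sample=True)
    # linear interpolation between samples k-1 and k
    y0, y1 = mag[k - 1], mag[k]
    frac = (y0 - half) / (y0 - y1) if y0 != y1 else 0.0
    t_half = float((k - 1 + frac) * dt)
    # a crossing inside the first sampling interval is below the
    # time resolution of the recording
    return TailMetrics(I_o=i_o, t_half=t_half, sub_sample=t_half < dt)


# ---------------------------------------------------------------------------
# G-V construction and fitting


def steady_iv(
    recording: Recording,
    test_epoch: int,
    window_ms: float = 5.0,
) -> IVCurve:
    """Isochronal steady-state I-V across sweeps of the test epoch."""
    sl = recording.epoch_slice(test_epoch)
    v = np.array(
        [recording.protocol.epoch_voltage(test_epoch, s)[0]
         for s in range(recording.n_sweeps)]
    )
    i = np.array(
        [
            isochronal_current(recording.currents[s, sl], recording.dt, window_ms)
            for s in range(recording.n_sweeps)
        ]
    )
    return IVCurve(voltages=v, currents=i, kind="steady")


def derive_gv(
    iv: IVCurve,
    v_rev: float,
    exclusion_mV: float = 5.0,
) -> GVCurve:
    """Conductance-voltage relation G(V) = I(V)/(V - V_rev), normalized.

    Points within ``exclusion_mV`` of the reversal potential are masked
    (the quotient is ill-conditioned there).  For instantaneous-tail IVs the
    tail amplitudes are already proportional to conductance, so they are
    normalized directly.
    """
    v = iv.voltages
    if iv.kind == "instantaneous-tail":
        g = iv.currents.astype(float).copy()
        keep = np.ones(v.size, dtype=bool)
    else:
        keep = np.abs(v - v_rev) >= exclusion_mV
        if not np.any(keep):
            raise ValueError("all I-V points fall inside the exclusion window")
        g = np.full(v.size, np.nan)
        g[keep] = iv.currents[keep] / (v[keep] - v_rev)
    gk = g[keep]
    gmax = np.max(np.abs(gk))
    if gmax == 0:
        raise ValueError("all conductances are zero; cannot normalize")
    # sign convention: conductance is positive
    sign = np.sign(gk[np.argmax(np.abs(gk))])
    return GVCurve(
        voltages=v[keep],
        g=gk * sign,
        g_norm=gk * sign / gmax,
        v_rev=v_rev,
        excluded_voltages=v[~keep],
        kind=iv.kind,
    )


def eval_boltzmann(V, v_half: float, s: float):
    """Boltzmann activation curve G/G_max = 1/(1 + exp((V1/2 - V)/s))."""
    if s == 0:
        raise ValueError("slope parameter s must be nonzero")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp((v_half - V) / s))
    return float(out) if out.ndim == 0 else out


def fit_boltzmann(gv: GVCurve, init: tuple | None = None) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a (normalized) G-V curve.

    Initialization: V1/2 from the half-maximum crossing, s from the 10-90%
    rise width (width = s * 2 ln 9), G_max from the plateau.  Uncertainties
    are square roots of the covariance diagonal at the optimum.
    """
    v = np.asarray(gv.voltages, dtype=float)
    y = np.asarray(gv.g_norm, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 G-V points spanning the rising phase")
    order = np.argsort(v)
    v, y = v[order], y[order]
    if linregress(v, y).slope < 0:
        raise FitError(
            "conductance decreases with voltage; refusing to fit an "
            "activation Boltzmann"
        )
    if init is None:
        gmax0 = float(np.max(y))
        yn = y / gmax0
        v_half0 = float(np.interp(0.5, np.clip(yn, 0, 1), v))
        v10 = float(np.interp(0.1, np.clip(yn, 0, 1), v))
        v90 = float(np.interp(0.9, np.clip(yn, 0, 1), v))
        s0 = max((v90 - v10) / (2.0 * np.log(9.0)), 0.1)
        init = (v_half0, s0, gmax0)

    def model(vv, v_half, s, g_max):
        return g_max / (1.0 + np.exp((v_half - vv) / s))

    try:
        popt, pcov = curve_fit(model, v, y, p0=init, maxfev=20_000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(v, *popt)
    return BoltzmannFit(
        v_half=float(popt[0]),
        s=float(popt[1]),
        g_max=float(popt[2]),
        v_half_err=float(perr[0]),
        s_err=float(perr[1]),
        g_max_err=float(perr[2]),
        residual_norm=float(np.linalg.norm(resid)),
    )


# ---------------------------------------------------------------------------
# selectivity


def estimate_reversal(tail_iv: IVCurve) -> float:
    """Reversal potential from instantaneous tail currents, mV.

    Requires tail amplitudes bracketing a sign change; the crossing is
    located by linear interpolation (a local linear fit over the two points
    on either side of the crossing when more are available).
    """
    order = np.argsort(tail_iv.voltages)
    v = tail_iv.voltages[order]
    i = tail_iv.currents[order]
    sign_change = np.where(np.diff(np.sign(i)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("tail currents do not bracket a sign change")
    k = sign_change[0]
    lo = max(0, k - 1)
    hi = min(v.size, k + 3)
    if hi - lo > 2:
        res = linregress(v[lo:hi], i[lo:hi])
        return float(-res.intercept / res.slope)
    # exactly two points: straight interpolation
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def selectivity_fit(
    vrev_by_dpH: dict[float, "float | list[float] | np.ndarray"],
    T: float | None = None,
) -> SelectivityFit:
    """OLS of V_rev against DpH, with the perfect-selectivity reference.

    A perfectly proton-selective channel follows E_H = -ln(10)(RT/F) DpH
    (-58.9 mV per pH unit at 297 K); the fitted slope is compared with that
    line.
    """
    from .constants import T_REF

    T = T_REF if T is None else T
    if len(vrev_by_dpH) < 3:
        raise ValueError("need >= 3 distinct DpH values for a selectivity fit")
    xs, ys, means = [], [], {}
    for dph, vals in sorted(vrev_by_dpH.items()):
        vals = np.atleast_1d(np.asarray(vals, dtype=float))
        means[dph] = float(vals.mean())
        xs.extend([dph] * vals.size)
        ys.extend(vals.tolist())
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
    else:
        res = linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    ns = nernst_slope(T)
    return SelectivityFit(
        slope=slope,
        intercept=intercept,
        mean_vrev=means,
        nernst_slope=ns,
        deviation=slope - (-ns),
    )


# ---------------------------------------------------------------------------
# DpH dependence of gating


def dpH_shift_analysis(
    fits_by_condition: dict[float, BoltzmannFit],
    threshold: float = 0.02,
) -> DpHShiftResult:
    """V1/2 shift per unit change in DpH across fitted conditions.

    ``fits_by_condition`` maps DpH to a Boltzmann fit.  For every condition
    pair the ratio dV1/2 / dDpH is reported, together with the activation
    threshold voltage of each condition (where the normalized conductance
    crosses ``threshold``) and the -40 mV/pH shift an animal-like channel
    would show.
    """
    dphs = sorted(fits_by_condition)
    if len(dphs) < 2:
        raise ValueError("need fits for at least two DpH conditions")
    if len(set(dphs)) != len(dphs):
        raise ValueError("conditions with identical DpH")
    shifts: dict[tuple[float, float], float] = {}
    expected: dict[tuple[float, float], float] = {}
    for a_i in range(len(dphs)):
        for b_i in range(a_i + 1, len(dphs)):
            a, b = dphs[a_i], dphs[b_i]
            ddph = b - a
            if ddph == 0:
                raise ValueError("conditions with identical DpH")
            dv = fits_by_condition[b].v_half - fits_by_condition[a].v_half
            shifts[(a, b)] = dv / ddph
            expected[(a, b)] = -40.0
    v_thr = {
        dph: fit.v_half - fit.s * np.log(1.0 / threshold - 1.0)
        for dph, fit in fits_by_condition.items()
    }
    return DpHShiftResult(
        shift_per_dpH=shifts,
        v_threshold=v_thr,
        expected_animal_shift=expected,
        mean_shift_per_dpH=float(np.mean(list(shifts.values()))),
    )


# ---------------------------------------------------------------------------
# gating charge


def limiting_slope_zg(
    po: np.ndarray,
    V: np.ndarray,
    po_max: float = 0.02,
    T: float | None = None,
) -> ZgEstimate:
    """Limiting-slope gating charge from ln(P_o) vs V at very low P_o.

    P_o is measured as G/G_max; on the window 0 < P_o <= po_max an OLS line
    is fitted to ln(P_o) against V and the total gating charge is
    z_g = (k_B T / e0) * slope.
    """
    from .constants import T_REF

    T = T_REF if T is None else T
    po = np.asarray(po, dtype=float)
    V = np.asarray(V, dtype=float)
    window = (po > 0) & (po <= po_max)
    if not np.any(po <= po_max):
        raise ValueError("po_max excludes every point")
    n = int(window.sum())
    if n < 5:
        raise ValueError(
            f"need >= 5 points with 0 < P_o <= {po_max}; got {n}"
        )
    res = linregress(V[window], np.log(po[window]))
    vt = thermal_voltage(T)
    return ZgEstimate(
        z_g=float(vt * res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        po_max=po_max,
        n_points=n,
        T=T,
    )


# ---------------------------------------------------------------------------
# pharmacology


def inhibition_fraction(I_control: float, I_drug: float) -> float:
    """Percent inhibition 100 (1 - I_drug/I_control) from isochronal currents.

    Uses magnitudes of the channel-mediated currents; control and drug
    currents must have the same sign (same driving-force direction).
    """
    if I_control == 0:
        raise ValueError("control current is zero")
    if I_drug != 0 and np.sign(I_drug) != np.sign(I_control):
        raise ValueError("control and drug currents have opposite signs")
    return float(100.0 * (1.0 - abs(I_drug) / abs(I_control)))


def tau_ratio(fit_plus: ExpFit, fit_minus: ExpFit) -> float:
    """Activation-kinetics ratio tau_on(+)/tau_on(-).

    Ratios above 1 indicate inhibitor-induced deceleration of opening, the
    signature of closed-state stabilization.
    """
    if fit_plus is None or fit_minus is None:
        raise ValueError("both exponential fits are required")
    return float(fit_plus.tau_on / fit_minus.tau_on)


def tail_iv(
    recording: Recording,
    tail_epoch: int,
    blank_ms: float = BLANK_MS,
    window_samples: int = 2,
) -> IVCurve:
    """Instantaneous tail I-V: current right after repolarization, per sweep.

    The first ``blank_ms`` after the voltage change are discarded
    (capacitive transient); the tail amplitude is the mean of the next
    ``window_samples`` samples.  Voltages are the per-sweep tail voltages.
    """
    sl = recording.epoch_slice(tail_epoch)
    blank = int(round(blank_ms / recording.dt))
    v = np.array(
        [
            recording.protocol.epoch_voltage(tail_epoch, s)[0]
            for s in range(recording.n_sweeps)
        ]
    )
    i = np.array(
        [
            float(
                np.mean(
                    recording.currents[s, sl][blank : blank + window_samples]
                )
            )
            for s in range(recording.n_sweeps)
        ]
    )
    return IVCurve(voltages=v, currents=i, kind="instantaneous-tail")
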