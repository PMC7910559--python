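"""Channel-variant preset library.

Each preset is a YAML file shipped with the package describing one channel
construct: the wild-type fungal channels SlHv1 (Suillus luteus) and AoHv1
(Aspergillus oryzae), a human-like reference (hHv1), the SlHv1/AoHv1
chimeras (ChL1-2 family, ChL2-3, ChL3-4, ChCT1-3, and the double chimera
ChL1-2b+L3-4), and a sequential three-state SlHv1-like variant used for
limiting-slope gating-charge work.

Boltzmann parameters (V1/2, s) are the published fit values for each
construct; pH couplings, kinetics, and conductance are simulation choices
documented in the package methods note.  For two-state presets the gating
charge is tied to the slope (z = k_B T/(e0 s)) and the rate prefactor is
chosen so that the activation time constant at the stated reference voltage
matches tau_on_ms.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .constants import T_REF, thermal_voltage
from .model import ChannelModel, GatingScheme, Solutions, effective_v_half

__all__ = ["available_presets", "load_preset", "preset_parameters"]

_DATA_PACKAGE = "hvkit.data.presets"


def _preset_files() -> dict[str, str]:
    files = {}
    for entry in resources.files(_DATA_PACKAGE).iterdir():
        if entry.name.endswith(".yaml"):
            files[entry.name[: -len(".yaml")]] = entry.name
    return files


def available_presets() -> list[str]:
    """Names of all shipped presets (case-sensitive)."""
    names = []
    for fname in sorted(_preset_files().values()):
        text = resources.files(_DATA_PACKAGE).joinpath(fname).read_text()
        names.append(yaml.safe_load(text)["name"])
    return sorted(names)


def preset_parameters(name: str) -> dict:
    """Raw parameter dictionary of a preset, as stored in its YAML file."""
    for fname in _preset_files().values():
        text = resources.files(_DATA_PACKAGE).joinpath(fname).read_text()
        params = yaml.safe_load(text)
        if params["name"].lower() == name.lower():
            return params
    raise KeyError(
        f"unknown preset {name!r}; available: {', '.join(available_presets())}"
    )


def _rate_prefactors(
    z_steps: tuple[float, ...],
    v_half: float,
    tau_on: float,
    tau_ref_v: float,
    T: float = T_REF,
) -> tuple[float, ...]:
    """Prefactors giving a per-transition relaxation of ~tau_on/(n steps)
    at the reference voltage (exact for a two-state scheme)."""
    vt = thermal_voltage(T)
    n = len(z_steps)
    # the offset V0 equals v_half for two-state schemes; for longer schemes
    # it is close enough for rate calibration purposes
    per_step_tau = tau_on / n
    out = []
    for z in z_steps:
        x = z * (tau_ref_v - v_half) / (2.0 * vt)
        out.append(1.0 / (per_step_tau * 2.0 * np.cosh(x)))
    return tuple(out)


def load_preset(name: str, T: float = T_REF) -> ChannelModel:
    """Build the :class:`~hvkit.model.ChannelModel` for a named preset."""
    p = preset_parameters(name)
    s = float(p["slope_mV"])
    vt = thermal_voltage(T)
    n_states = int(p.get("n_states", 2))
    if n_states == 2:
        z_steps: tuple[float, ...] = (vt / abs(s),)
    else:
        z_total = float(p["z_total"])
        z_steps = tuple([z_total / (n_states - 1)] * (n_states - 1))
    rate0 = _rate_prefactors(
        z_steps,
        float(p["v_half_mV"]),
        float(p["tau_on_ms"]),
        float(p["tau_ref_mV"]),
        T,
    )
    return ChannelModel(
        g_max=float(p.get("g_max_nS", 100.0)),
        v_half_ref=float(p["v_half_mV"]),
        s=s,
        c_dpH=float(p.get("c_dpH_mV_per_pH", 0.0)),
        c_sym=float(p.get("c_sym_mV_per_pH", 0.0)),
        scheme=GatingScheme(z_step=z_steps, rate0=rate0),
        m_act=n_states - 1,
        label=p["name"],
    )
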