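"""pH dependence of gating: DpH coupling and symmetric-pH sensitivity.

Fungal Hv channels shift their activation range far more per unit of
transmembrane pH gradient (~85-90 mV/pH) than the ~40 mV/pH canonical for
animal Hvs, and SlHv1 additionally shifts ~19 mV per pH unit when both
sides change together (DpH = 0), where most Hvs are insensitive.
"""

import numpy as np

from hvkit import Solutions, dpH_shift_analysis
from hvkit.presets import load_preset
from hvkit.recipes import fit_gv_from_recording, symmetric_ph_slope
from hvkit.orchestrator import _simulate_stage, AnalysisConfig

# --- DpH coupling: fit G-V at DpH = 0 and +1 (pH_i perfused 6.0 -> 5.0)
fits = {}
for dph, ph_i in ((0.0, 6.0), (1.0, 5.0)):
    cfg = AnalysisConfig.from_dict(
        {"simulate": {"preset": "SlHv1", "pH_i": ph_i, "pH_o": 6.0}, "seed": 4}
    )
    fits[dph] = fit_gv_from_recording(_simulate_stage(cfg))
res = dpH_shift_analysis(fits)
shift = res.shift_per_dpH[(0.0, 1.0)]
print(f"V1/2 at DpH 0:  {fits[0.0].v_half:6.1f} mV")
print(f"V1/2 at DpH 1:  {fits[1.0].v_half:6.1f} mV")
print(f"shift: {shift:.0f} mV per pH unit "
      f"(animal-like expectation: {res.expected_animal_shift[(0.0, 1.0)]:.0f})")

# --- symmetric-pH sensitivity
slope, means = symmetric_ph_slope("SlHv1", phs=(5.5, 6.0, 6.5), seed=0)
print()
for ph, v in means.items():
    print(f"pH_i = pH_o = {ph}:  V1/2 = {v:5.1f} mV")
print(f"symmetric-pH slope: {slope:.1f} mV per pH unit")
print()
print("The DpH shift dwarfs the 40 mV/pH animal benchmark, while the")
print("symmetric-pH slope reproduces the distinct ~19 mV/pH sensitivity.")
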