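name: hHv1
v_half_mV: 53.0
slope_mV: 11.6
g_max_nS: 100.0
c_dpH_mV_per_pH: -40.0
c_sym_mV_per_pH: 0.0
tau_on_ms: 200.0
tau_ref_mV: 60.0
description: Human Hv1-like reference with the canonical ~40 mV/pH gradient coupling.
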