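name: ChL1-2
v_half_mV: 11.4
slope_mV: 11.0
g_max_nS: 100.0
c_dpH_mV_per_pH: -85.0
c_sym_mV_per_pH: 19.0
tau_on_ms: 60.0
tau_ref_mV: 60.0
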