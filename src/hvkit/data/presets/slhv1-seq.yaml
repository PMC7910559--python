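name: SlHv1-seq
v_half_mV: 46.5
slope_mV: 7.6
g_max_nS: 100.0
c_dpH_mV_per_pH: -85.0
c_sym_mV_per_pH: 19.0
tau_on_ms: 50.0
tau_ref_mV: 46.5
n_states: 3
z_total: 5.0
description: Sequential three-state SlHv1-like scheme with total gating charge 5 e0,
  for limiting-slope work; its activation shows a sigmoidal lag.
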