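name: ChL2-3
v_half_mV: 90.0
slope_mV: 15.3
g_max_nS: 100.0
c_dpH_mV_per_pH: -85.0
c_sym_mV_per_pH: 0.0
tau_on_ms: 300.0
tau_ref_mV: 90.0
description: S2-S3 intracellular loop swap; loses the symmetric-pH sensitivity of
  SlHv1.
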