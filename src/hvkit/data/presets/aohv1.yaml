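name: AoHv1
v_half_mV: -13.9
slope_mV: 7.4
g_max_nS: 100.0
c_dpH_mV_per_pH: -90.0
c_sym_mV_per_pH: 0.0
tau_on_ms: 50.0
tau_ref_mV: -10.0
description: Wild-type Hv1 from Aspergillus oryzae (Ascomycota); opens at negative
  potentials and carries inward proton current.
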