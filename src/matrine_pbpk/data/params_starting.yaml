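# Literature-derived starting values used before parameter optimization.
Qcar: 4.944
PCV: 0.333
Qc_l: 0.3
Qc_ot: 0.7
Vc_int: 0.01
Vc_l: 0.0294
Vc_b: 0.06
Vc_ot: 0.9006
k_st: 0.1
k_a: 0.3
F: 0.171
P_l: 5.5
P_ot: 5.0
k_e: 0.01
k_bi: 0.01
Pb: 0.3
Cl_renal: 1.182
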