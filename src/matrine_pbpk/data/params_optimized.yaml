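# Optimized parameter values for matrine in the pig intestinal-lumen PBPK model.
Qcar: 4.944        # cardiac output, L/(h*kg BW)
PCV: 0.333         # hematocrit (carried, enters no equation)
Qc_l: 0.3          # liver blood flow, fraction of Qcar
Qc_ot: 0.7         # other-organs blood flow, fraction of Qcar
Vc_int: 0.0136733  # intestinal-content volume, fraction of BW
Vc_l: 0.0294       # liver volume, fraction of BW
Vc_b: 0.06         # blood volume, fraction of BW
Vc_ot: 0.8969267   # other-organs volume, fraction of BW (balancing term)
k_st: 0.8544925    # gastric-emptying rate, 1/h
k_a: 0.8555538     # absorption rate constant, 1/h
F: 0.7925891       # oral bioavailability
P_l: 2.936615      # liver-to-blood partition coefficient
P_ot: 11.33514     # other-organs-to-blood partition coefficient
k_e: 0.007358172   # fecal excretion rate constant, 1/h
k_bi: 0.05834594   # biliary excretion rate constant, 1/h
Pb: 0.319          # plasma protein binding fraction
Cl_renal: 0.2805897  # renal clearance, L/(h*kg BW)
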