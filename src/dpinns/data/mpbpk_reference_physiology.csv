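parameter,value,unit,description
reference_weight,70.0,kg,Reference human body weight
V_plasma,2.6,L,Plasma volume
V_lymph,5.2,L,Total lymph volume
V_isf_total,15.6,L,Total interstitial fluid volume
isf_availability,0.8,-,Fraction of ISF accessible to IgG-type antibodies
tight_fraction,0.65,-,Fraction of accessible ISF in continuous-endothelium (tight) tissues
L_total,0.12083333333333333,L/h,Total lymph flow (2.9 L/day)
L1_fraction,0.33,-,Fraction of lymph flow perfusing tight tissues
sigma_L,0.2,-,Lymphatic capillary reflection coefficient
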