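# Published ten-salt recipe (mg/L) that reconstructs the loamy-soil solution's
# ion composition (calcium is delivered at its mass-balance level, not the
# published soil value; see docs/methods.md).
salt,mg_per_l
(NH4)2SO4,26.43005
Ca(OH)2,16.67094
CaSO4.2H2O,391.7074
K2SO4,26.139
Mg(NO3)2.6H2O,602.6105
MgCl2.6H2O,193.164
MgSO4.7H2O,24.64998
Na2FeEDTA.2H2O,8.521155
Na2HPO4,0.7098
Na2SO4,95.8902
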