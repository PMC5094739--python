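# Built-in salt catalog: MS-type macro/micronutrient salts, hydroxides, and
# the chloride salts needed for classic K/Na substitution experiments.
# Order is significant (deterministic tie-break among equally optimal recipes).
name,formula,dissociation,weight,molar_mass_override,note
KNO3,KNO3,K+:1;NO3-:1,1,,
NH4NO3,NH4NO3,NH4+:1;NO3-:1,1,,
(NH4)2SO4,(NH4)2SO4,NH4+:2;SO4 2-:1,1,,
NH4OH,NH4OH,NH4+:1;OH-:1,1,,taken at face value as NH4+ + OH-
KH2PO4,KH2PO4,K+:1;H2PO4-:1,1,,
K2SO4,K2SO4,K+:2;SO4 2-:1,1,,
KCl,KCl,K+:1;Cl-:1,1,,
KI,KI,K+:1;I-:1,1,,
NaNO3,NaNO3,Na+:1;NO3-:1,1,,
Na2SO4,Na2SO4,Na+:2;SO4 2-:1,1,,
Na3PO4,Na3PO4,Na+:3;PO4 3-:1,1,,
Na2HPO4,Na2HPO4,Na+:2;HPO4 2-:1,1,,
NaH2PO4,NaH2PO4,Na+:1;H2PO4-:1,1,,
NaOH,NaOH,Na+:1;OH-:1,1,,
NaCl,NaCl,Na+:1;Cl-:1,1,,
CaCl2.2H2O,CaCl2.2H2O,Ca2+:1;Cl-:2,1,,
CaSO4.2H2O,CaSO4.2H2O,Ca2+:1;SO4 2-:1,1,,
Ca(OH)2,Ca(OH)2,Ca2+:1;OH-:2,1,,
MgSO4.7H2O,MgSO4.7H2O,Mg2+:1;SO4 2-:1,1,,
MgCl2.6H2O,MgCl2.6H2O,Mg2+:1;Cl-:2,1,,
Mg(NO3)2.6H2O,Mg(NO3)2.6H2O,Mg2+:1;NO3-:2,1,,
Na2FeEDTA.2H2O,C10H12FeN2Na2O8.2H2O,Na+:2;Fe2+:1;EDTA 4-:1,1,426.06,effective mass implied by published mg/L usage; Fe(II)/EDTA4- charge convention
Na2EDTA.2H2O,C10H14N2Na2O8.2H2O,Na+:2;EDTA 2-:1,1,,
FeSO4.7H2O,FeSO4.7H2O,Fe2+:1;SO4 2-:1,1,,
MnSO4.4H2O,MnSO4.4H2O,Mn2+:1;SO4 2-:1,1,,
ZnSO4.4H2O,ZnSO4.4H2O,Zn2+:1;SO4 2-:1,1,,
H3BO3,H3BO3,BO3 3-:1;H+:3,1,,
CuSO4.5H2O,CuSO4.5H2O,Cu2+:1;SO4 2-:1,1,,
Na2MoO4.2H2O,Na2MoO4.2H2O,Na+:2;MoO4 2-:1,1,,
CoCl2.6H2O,CoCl2.6H2O,Co2+:1;Cl-:2,1,,
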