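# Published whole-mg recipes (mg/L) that realized the five K+/Na+ substitution
# media.  Columns are ordered by descending K+ (r1 = K-rich vertex): recipe
# column r_i realizes target medium 6-i of ms_kna_design_targets.csv.  The
# realized K+/Na+ levels carry a 0.2 mM floor on each component (vertices at
# 23/0.2 rather than 23.2/0); micronutrient salts (constant across media) are
# excluded.
salt,r1,r2,r3,r4,r5
(NH4)2SO4,13,0,0,0,0
CaCl2.2H2O,441,441,441,441,441
KH2PO4,170,51,51,51,27
KNO3,2199,1711,1135,559,0
MgSO4.7H2O,370,370,370,370,370
Na2SO4,0,14,14,14,14
Na3PO4,0,143,143,143,143
NaH2PO4,0,0,0,0,21
NaNO3,0,261,746,1230,1700
NaOH,8,0,0,0,0
NH4NO3,1461,1601,1601,1601,1601
NH4OH,54,0,0,0,0
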