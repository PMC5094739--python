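# Published two-salt (KCl/NaCl) wheat experiment, deconstructed into the ions
# actually varied: every treatment co-varies Cl- with K+ and Na+ (ion
# confounding).  Ion columns and totals are the published deconstruction.
treatment,KCl_mM,NaCl_mM,K_mM,Na_mM,Cl_mM,total_mM,pH
1,0.54,0,0.54,0,0.54,1.08,5.6
2,0.54,1.1,0.54,1.1,1.64,3.28,5.6
3,0.54,2.2,0.54,2.2,2.74,5.48,5.6
4,0.54,4.3,0.54,4.3,4.84,9.68,5.6
5,0.54,8.7,0.54,8.7,9.24,18.48,5.6
6,1.34,0,1.34,0,1.34,2.68,5.6
7,1.34,1.1,1.34,1.1,2.44,4.88,5.6
8,1.34,2.2,1.34,2.2,3.54,7.08,5.6
9,1.34,4.3,1.34,4.3,5.64,11.28,5.6
10,1.34,8.7,1.34,8.7,10.04,20.08,6.9
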