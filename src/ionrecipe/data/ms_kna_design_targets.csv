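# Target ion levels (mM) of the five K+/Na+ substitution media: the K+/Na+
# pool (23.2 mM total, the MS level plus a 2.95 mM Na+ pH-adjustment offset)
# is blended while all other MS macro-ions are held constant.
medium,Na_mM,K_mM,NH4_mM,NO3_mM,PO4_mM,Ca_mM,Mg_mM,SO4_mM,Cl_mM,total_mM
1,23.2,0,20,40,1.25,3,1.5,1.6,6,96.55
2,17.4,5.8,20,40,1.25,3,1.5,1.6,6,96.55
3,11.6,11.6,20,40,1.25,3,1.5,1.6,6,96.55
4,5.8,17.4,20,40,1.25,3,1.5,1.6,6,96.55
5,0,23.2,20,40,1.25,3,1.5,1.6,6,96.55
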