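# Ionic composition of a loamy agricultural soil solution (neutral pH), the
# published hand-formulated "soil solution equivalent" (SSE) approximation of
# it, and the published per-ion percent deviation of the SSE from the target.
ion,soil_mM,sse_mM,sse_pct_dev
NO3-,4.7,2.5,-47
NH4+,0.4,2.5,525
PO4_total,0.005,0.005,0
Na+,1.4,2.5,79
Ca2+,12.4,4.0,-68
Mg2+,3.4,2.0,-41
K+,0.3,0.503,68
Cl-,1.9,4.0,111
SO4 2-,3.4,5.0,47
Fe_total,0.02,0.2,900
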