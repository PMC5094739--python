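# Observed fresh-weight growth (% increase over initial weight, 14 d, mean of
# 6 dishes per design point) of a citrus nonembryogenic cell line on the
# 13-point K+/Na+ mixture design (proportions of the 23.2 mM K+Na pool).
point,x_na,x_k,growth_pct
1,0.75,0.25,1038
2,0.5,0.5,1082
3,1,0,217
4,1,0,196
5,0.5,0.5,1317
6,0.25,0.75,1031
7,0.75,0.25,906
8,0,1,867
9,1,0,215
10,0,1,1125
11,0.5,0.5,1021
12,0,1,1146
13,0.25,0.75,1209
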