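site,length_km,area_km2,gradient_pct,precipitation_mm,temperature_C,runoff_1e8m3,altitude_m
XR,291,,0.0895,1418,21.6,1230,25
YYR,426,20593,0.0199,1320,21.6,410,65
HR,352,11536,0.0580,1555,21.7,112,90
LGR,426,19288,0.0247,1890,19.8,42,103
LR,773,51713,0.0168,1600,19.0,410,99.3
HSR,659,52600,0.0380,1100,18.0,696,242
YR,707,38612,0.0280,1187,17.1,172,120
ZR,346,32068,0.0366,1300,20.7,174,89
NLR,287,9232,0.0377,1458,21.9,77,46
OR,692,17322,0.0354,1386,22.0,62,58
XZR,221,3414,0.0360,1236,17.0,44.9,225
BDR,62,1758,0.0700,1465,19.2,12,358
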