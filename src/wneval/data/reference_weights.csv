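indicator,year,e,d,w_pct
ET,2022,0.844,0.156,21.78
Y,2022,0.890,0.110,15.42
WUE,2022,0.841,0.159,22.20
NPFP,2022,0.914,0.086,12.04
TSS,2022,0.905,0.095,13.32
VC,2022,0.891,0.109,15.24
ET,2023,0.861,0.139,19.12
Y,2023,0.852,0.148,20.33
WUE,2023,0.857,0.143,19.67
NPFP,2023,0.916,0.084,11.53
TSS,2023,0.900,0.100,13.78
VC,2023,0.886,0.114,15.58
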