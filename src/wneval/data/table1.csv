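treatment,year,et_mm,yield_t_ha
W1N1,2022,275.88,63.57
W2N1,2022,289.92,72.12
W3N1,2022,321.02,72.74
W1N2,2022,271.40,66.15
W2N2,2022,298.07,87.87
W3N2,2022,333.13,85.60
W1N3,2022,266.73,58.81
W2N3,2022,301.60,77.23
W3N3,2022,337.19,79.32
CK,2022,314.44,65.06
W1N1,2023,268.78,62.22
W2N1,2023,282.24,70.04
W3N1,2023,314.97,70.99
W1N2,2023,264.24,67.56
W2N2,2023,291.54,86.50
W3N2,2023,334.62,84.97
W1N3,2023,254.90,61.38
W2N3,2023,287.71,78.38
W3N3,2023,330.07,80.28
CK,2023,307.99,63.18
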