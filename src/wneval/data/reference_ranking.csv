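treatment,year,d_plus,d_minus,closeness,rank
W1N1,2022,0.717,0.392,0.353,8
W2N1,2022,0.541,0.534,0.497,4
W3N1,2022,0.623,0.556,0.472,5
W1N2,2022,0.655,0.514,0.440,6
W2N2,2022,0.261,0.898,0.775,1
W3N2,2022,0.272,0.805,0.748,2
W1N3,2022,0.971,0.066,0.064,9
W2N3,2022,0.615,0.438,0.416,7
W3N3,2022,0.490,0.658,0.573,3
W1N1,2023,0.773,0.326,0.297,8
W2N1,2023,0.550,0.502,0.478,6
W3N1,2023,0.707,0.443,0.385,7
W1N2,2023,0.565,0.533,0.485,4
W2N2,2023,0.179,0.951,0.841,1
W3N2,2023,0.270,0.830,0.754,2
W1N3,2023,0.956,0.121,0.112,9
W2N3,2023,0.571,0.532,0.482,5
W3N3,2023,0.456,0.619,0.576,3
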