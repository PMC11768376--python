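treatment,year,sp_mg_g,ssc_pct,tss_pct,vc_mg_kg
W1N1,2022,2.42,2.10,4.44,52.64
W2N1,2022,2.51,2.97,4.51,51.62
W3N1,2022,2.19,2.52,4.19,47.38
W1N2,2022,2.81,3.25,4.78,60.25
W2N2,2022,3.04,3.41,4.92,63.39
W3N2,2022,2.88,3.34,4.72,58.57
W1N3,2022,1.82,1.98,3.90,41.24
W2N3,2022,2.03,2.47,4.13,44.41
W3N3,2022,2.59,2.86,4.56,54.50
CK,2022,2.10,2.73,4.26,45.43
W1N1,2023,2.56,2.47,4.53,53.93
W2N1,2023,2.59,2.88,4.57,55.12
W3N1,2023,2.35,2.60,4.30,48.57
W1N2,2023,2.79,2.91,4.83,62.26
W2N2,2023,3.09,3.15,5.00,69.41
W3N2,2023,2.86,3.13,4.80,60.48
W1N3,2023,2.04,2.45,4.07,43.21
W2N3,2023,2.17,2.70,4.27,47.38
W3N3,2023,2.66,2.89,4.60,56.31
CK,2023,2.32,2.66,4.33,46.19
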