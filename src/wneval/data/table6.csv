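treatment,water_level,n_rate_kg_ha,seedling_lo,seedling_hi,flowering_lo,flowering_hi,full_lo,full_hi,later_lo,later_hi,irrigation_2022_mm,irrigation_2023_mm
W1N1,W1,215,70,80,50,60,70,80,70,80,193,196
W2N1,W2,215,70,80,60,70,70,80,70,80,207,217
W3N1,W3,215,70,80,70,80,70,80,70,80,238,245
W1N2,W1,270,70,80,50,60,70,80,70,80,189,193
W2N2,W2,270,70,80,60,70,70,80,70,80,215,228
W3N2,W3,270,70,80,70,80,70,80,70,80,250,248
W1N3,W1,325,70,80,50,60,70,80,70,80,183,191
W2N3,W2,325,70,80,60,70,70,80,70,80,219,216
W3N3,W3,325,70,80,70,80,70,80,70,80,254,249
CK,CK-full,0,70,80,70,80,70,80,70,80,232,233
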