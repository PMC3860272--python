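species,delta_gf_kj_per_mol
SO4-2,-744.53
HS-,12.08
HCO3-,-586.77
H2O,-237.13
H+,0.0
CH4,-34.33
C2H6,-16.26
C3H8,-8.37
C4H10,-1.0
C5H12,8.0
CH3COO-,-369.31
H2,0.0
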