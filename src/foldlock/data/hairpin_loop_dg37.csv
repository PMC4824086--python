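# DNA hairpin loop closure penalties dG37 (kcal/mol) by loop size in nt
# (SantaLucia & Hicks 2004, Annu Rev Biophys 33:415, Table 4).
# Sizes above the largest tabulated entry are extrapolated at run time with
# the Jacobson-Stockmayer term dG(n) = dG(nmax) + 1.75*R*T*ln(n/nmax).
loop_len,dG37_kcal_mol
3,3.5
4,3.5
5,3.3
6,4.0
7,4.2
8,4.3
9,4.5
10,4.4
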