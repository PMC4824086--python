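# RNA/DNA hybrid nearest-neighbor parameters (Sugimoto et al. 1995,
# Biochemistry 34:11211). step: dinucleotide 5'->3' on the RNA strand,
# paired with its complementary DNA; the table is NOT symmetric.
# Units: dH kcal/mol, dS cal/(mol K), dG37 kcal/mol at 1 M NaCl.
step,dH_kcal_mol,dS_cal_mol_K,dG37_kcal_mol
AA,-7.8,-21.9,-1.0
AC,-5.9,-12.3,-2.1
AG,-9.1,-23.5,-1.8
AU,-8.3,-23.9,-0.9
CA,-9.0,-26.1,-0.9
CC,-9.3,-23.2,-2.1
CG,-16.3,-47.1,-1.7
CU,-7.0,-19.7,-0.9
GA,-5.5,-13.5,-1.3
GC,-8.0,-17.1,-2.7
GG,-12.8,-31.9,-2.9
GU,-7.8,-21.6,-1.1
UA,-7.8,-23.2,-0.6
UC,-8.6,-22.9,-1.5
UG,-10.4,-28.4,-1.6
UU,-11.5,-36.4,-0.2
init,1.9,-3.9,3.1
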