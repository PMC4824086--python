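# DNA/DNA nearest-neighbor parameters (Sugimoto et al. 1996, NAR 24:4501).
# step: dinucleotide 5'->3' on one strand, paired with its Watson-Crick
# complement; the table is symmetric (XY == reverse-complement lookup).
# Units: dH kcal/mol, dS cal/(mol K), dG37 kcal/mol at 1 M NaCl.
step,dH_kcal_mol,dS_cal_mol_K,dG37_kcal_mol
AA,-8.0,-21.9,-1.2
AT,-5.6,-15.2,-0.9
TA,-6.6,-18.4,-0.9
CA,-8.2,-21.0,-1.7
GT,-9.4,-25.5,-1.5
CT,-6.6,-16.4,-1.5
GA,-8.8,-23.5,-1.5
CG,-11.8,-29.0,-2.8
GC,-10.5,-26.4,-2.3
GG,-10.9,-28.4,-2.1
init,0.6,-9.0,3.4
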