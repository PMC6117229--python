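# Ordered tautomer/mesomer normalization rules, applied top-to-bottom to a
# fixpoint (max iterations set in StandardizationConfig). One rule per line:
#   name <TAB> reaction SMARTS (single reactant -> single product)
# Mesomer rules move formal charges only; tautomer rules move hydrogens.
# Every rule must conserve the molecular formula.
nitro_mesomer	[N;X3;v5:1](=[O:2])=[O:3]>>[N+:1](=[O:2])[O-:3]
azide_mesomer	[N;X2:1]=[N;X2;v5:2]=[N;X1:3]>>[N:1]=[N+:2]=[N-:3]
azide_terminal_mesomer	[N;X1;v5:1]#[N;X2:2]=[N;X2:3]>>[N-:1]=[N+:2]=[N:3]
enol_keto	[C;!$(C=[!#6]);!$(C[OH]):1]=[C:2]-[O;X2;H1;!$(O[!#6]):3]>>[C:1]-[C:2]=[O:3]
enamine_imine	[C;!$(C=[!#6]):1]=[C:2]-[N;X3;H1;!$(N[!#6;!#1]);!$(N-[#6]=[!#6]):3]>>[C:1]-[C:2]=[N:3]
ynol_ketene	[C:1]#[C:2]-[O;X2;H1:3]>>[C:1]=[C:2]=[O:3]
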