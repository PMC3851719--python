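# nearest-neighbor duplex parameters, turner2004 revision
# source: Turner-lab RNA folding parameters as distributed in ViennaRNA 2.x (rna_turner2004.par)
# stacks: Xia et al. 1998 / Mathews et al. 1999 compilation, Delta-G at 37 C, kcal/mol
# step notation: top dinucleotide 5'->3'; bottom dinucleotide 3'->5' aligned under it
key	top	bottom	dg37_kcal
stack	AA	UU	-0.90
stack	AC	UG	-2.20
stack	AG	UC	-2.10
stack	AG	UU	-0.60
stack	AU	UA	-1.10
stack	AU	UG	-1.40
stack	CA	GU	-2.10
stack	CC	GG	-3.30
stack	CG	GC	-2.40
stack	CG	GU	-1.40
stack	CU	GA	-2.10
stack	CU	GG	-2.10
stack	GA	CU	-2.40
stack	GA	UU	-1.30
stack	GC	CG	-3.40
stack	GC	UG	-2.50
stack	GG	CC	-3.30
stack	GG	CU	-1.50
stack	GG	UC	-2.10
stack	GG	UU	-0.50
stack	GU	CA	-2.20
stack	GU	CG	-2.50
stack	GU	UA	-1.40
stack	GU	UG	1.30
stack	UA	AU	-1.30
stack	UA	GU	-1.00
stack	UC	AG	-2.40
stack	UC	GG	-1.50
stack	UG	AC	-2.10
stack	UG	AU	-1.00
stack	UG	GC	-1.40
stack	UG	GU	0.30
stack	UU	AA	-0.90
stack	UU	AG	-1.30
stack	UU	GA	-0.60
stack	UU	GG	-0.50
initiation	-	-	4.10
terminal_au	-	-	0.50
symmetry	-	-	0.43
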