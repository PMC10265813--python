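gene	genome_pos	gene_pos	codon_pos	edit_type	codon_change	aa_change	depth	efficiency_pct
atpA	10866	1263	3	C->U	CUC->CUU	L->L	9	88.89
rps14	37798	80	2	C->U	UCA->UUA	S->L	50	92.00
rps14	37729	149	2	C->U	CCA->CUA	P->L	37	97.30
accD	59505	791	2	C->U	UCG->UUG	S->L	18	38.89
psaI	60728	83	2	C->U	UCU->UUU	S->F	13	84.62
psaI	60733	88	1	C->U	CAU->UAU	H->Y	13	69.23
petL	67058	5	2	C->U	CCU->CUU	P->L	42	80.95
rps18	69519	221	2	C->U	CCG->CUG	P->L	27	74.07
clpP1	71381	559	1	C->U	CAU->UAU	H->Y	14	100.00
psbB	74290	414	3	C->U	AUC->AUU	I->I	117	69.23
petB	77760	611	2	C->U	CCA->CUA	P->L	53	73.58
rpoA	80192	200	2	C->U	UCU->UUU	S->F	9	77.78
rpoA	79562	830	2	C->U	UCA->UUA	S->L	14	71.43
rpl16	83113	12	3	C->U	CCC->CCU	P->P	24	75.00
ndhD	118698	383	2	C->U	CCA->CUA	P->L	5	100.00
ndhA	121876	961	1	C->U	CCU->UCU	P->S	10	100.00
ndhA	121764	1073	2	C->U	UCC->UUC	S->F	12	91.67
ndhA	121876	2053	1	C->U	CCU->UCU	P->S	10	100.00
ndhA	121764	2165	2	C->U	UCC->UUC	S->F	12	91.67
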