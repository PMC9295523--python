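# Published degenerate binding-site patterns and predicted plastid RNA
# targets for chloroplastic PPR proteins of Agave angustifolia (transcripts
# AaPPR1-AaPPR20, nucleotide accessions OM156485-OM158065; chloroplast genome
# MW540498). One row per (protein, target) pair; ir=1 marks RNAs from genes
# duplicated in the inverted-repeat regions. AaPPR3, AaPPR4 and AaPPR20 were
# promiscuous (>60 targets each) and have no printed pattern or targets.
ppr_id	subfamily	pattern	gene	feature	target_sequence	ir
AaPPR1	PLS	U[AU]UUU[AU]U[CAU][AC]U[AU]UU[ACGU][ACGU]	ycf1	CDS	UAUUUUUCAUUUUCA	0
AaPPR2	PLS	[ACGU][ACGU][UCG][AU][UCG][UCG]A[UCG]G[UCG][AU]GAU[ACGU]	rpoC1	intron	UCUUUUAGGGAGAUA	0
AaPPR2	PLS	[ACGU][ACGU][UCG][AU][UCG][UCG]A[UCG]G[UCG][AU]GAU[ACGU]	rps12	intron	GCUUGGAGGGAGAUC	1
AaPPR5	PLS	[ACGU][CG]A[AU]GAAAA[AU]G[ACGU][AU]A[ACGU][GU]	trnK-UUU	intron	AGAAGAAAAUGGAAUU	0
AaPPR6	P	[UC][GC][GC]A[CU][CA]UAG[GU]	rps16	intron	UCGACAUAGU	0
AaPPR6	P	[UC][GC][GC]A[CU][CA]UAG[GU]	petN	CDS	UGGAUAUAGU	0
AaPPR6	P	[UC][GC][GC]A[CU][CA]UAG[GU]	atpE	CDS	UGGAUAUAGG	0
AaPPR10	P	[ACGU]C[ACGU]UUCC[ACGU]CC	rpoC1	CDS	UCCUUCCUCC	0
AaPPR10	P	[ACGU]C[ACGU]UUCC[ACGU]CC	psbC	CDS	GCGUUCCCCC	0
AaPPR10	P	[ACGU]C[ACGU]UUCC[ACGU]CC	petA	CDS	UCUUUCCCCC	0
AaPPR10	P	[ACGU]C[ACGU]UUCC[ACGU]CC	rrn23	exon	GCGUUCCGCC	1
AaPPR11	P	[UC][UC][ACGU]A[ACGU]U[ACGU][ACGU][ACGU][ACGU][ACGU][ACGU]C[ACGU][UC]UCUU[CU]U	ycf2	CDS	UUCAAUCCUUUUCCUUCUUCU	1
AaPPR13	P	[GU][ACGU][ACGU]C[ACGU][ACGU]G[ACGU][ACGU][ACGU]AUGU	atpA	CDS	UAUCCAGGAGAUGU	0
AaPPR13	P	[GU][ACGU][ACGU]C[ACGU][ACGU]G[ACGU][ACGU][ACGU]AUGU	rps14	CDS	UGGCAAGAAAAUGU	0
AaPPR13	P	[GU][ACGU][ACGU]C[ACGU][ACGU]G[ACGU][ACGU][ACGU]AUGU	trnI-GAU	intron	UGACCCGGAGAUGU	1
AaPPR13	P	[GU][ACGU][ACGU]C[ACGU][ACGU]G[ACGU][ACGU][ACGU]AUGU	ycf1	CDS	UCUCAAGCAUAUGU	0
AaPPR15	PLS	UUG[CU]CGC	rbcL	CDS	UUGCCGC	0
AaPPR15	PLS	UUG[CU]CGC	rpl33	CDS	UUGUCGC	0
AaPPR18	PLS	UC[GC]UAU[AU][CU][ACGU]G	ycf2	CDS	UCCUAUACGG	1
AaPPR18	PLS	UC[GC]UAU[AU][CU][ACGU]G	psbD	CDS	UCCUAUUUGG	0
AaPPR18	PLS	UC[GC]UAU[AU][CU][ACGU]G	psbC	CDS	UCGUAUUCUG	0
AaPPR18	PLS	UC[GC]UAU[AU][CU][ACGU]G	psaB	CDS	UCGUAUUUGG	0
AaPPR18	PLS	UC[GC]UAU[AU][CU][ACGU]G	ndhG	CDS	UCCUAUUUUG	0
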