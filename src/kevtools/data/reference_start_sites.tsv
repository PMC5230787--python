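locus	gene	group	kev	utr_len_untreated	utr_len_treated	sd_distance	sd_called	sd_site
b1809	yoaB	sensitive	0.25	31	31	5	yes	TGAGGACA
b1238	tdk	sensitive	0.34	34	34	3	no	GCCTGTGG
b3180	yhbY	sensitive	0.36	31	31	7	yes	TAAGCAAA
b1779	gapA	sensitive	0.37	36	36	5	no	GCTGGTGG
b2765	sscR	sensitive	0.37	24	24	4	no	TGTAGAGA
b1824	yobF	sensitive	0.39	27	27	5	no	TACAGTTC
b2412	zipA	sensitive	0.40	47	47	6	no	CAACAGAG
b3357	crp	sensitive	0.45	166	166	7	yes	AGAGGATA
b3357	crp	sensitive		68	68
b0762	ybhT	sensitive	0.47	193	193	5	yes	TCTGGAGT
b0762	ybhT	sensitive		22	22
b0947	ycbX	sensitive	0.48	25	25	5	yes	TGAGGACC
b2682	ygaZ	resistant	2.38	48	48	6	yes	TAAGCGTA
b0882	clpA	resistant	2.56	53	53	5	yes	GGGGGAGG
b0882	clpA	resistant		173	173
b4052	dnaB	resistant	2.61	31	28	6	no	TAACTCCA
b0081	mraZ	resistant	2.69	45	45	5	yes	GGGTGAGG
b3958	argC	resistant	2.74	118	118	4	no	TGAATAGC
b0850	ybjC	resistant	3.07	21	21	7	yes	TGCAGAGG
b2208	napF	resistant	3.61	77	77	6	yes	GATGGAAG
b3321	rpsJ	resistant	3.79	20	20	5	no	GAGCTCTG
b3179	rrmJ	resistant	5.21	67	67	6	no	CATGGGAA
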