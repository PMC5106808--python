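gene	chrom	pos	ref_codon	alt_codon	ref_aa	alt_aa	exon	sift	provean
Gcfc2	6	81923813	tCt	tTt	S	F	1/18	0.05	-2.5
Gcfc2	6	81933786	cCa	cAa	P	Q	5/18	0.02	1.05
Gcfc2	6	81941369	Cgg	Tgg	R	W	7/17	0	-5.41
Ccdc142	6	83107557	cCt	cTt	P	L	7/11	0.15	-2.97
Htra2	6	83053837	Ggg	Cgg	G	R	1/7	0	NA
Htra2	6	83054296	cCt	cTt	P	L	1/7	0	-2.04
Mogs	6	83118580	Cgc	Tgc	R	C	4/4	0.03	0.94
Rtkn	6	83151299	Ccc	Gcc	P	A	12/13	0.14	-4.41
Rtkn	6	83151312	gCc	gTc	A	V	11/12	0.03	-1.1
1700003E16Rik	6	83162665	aCc	aTc	T	I	4/4	0.01	-1.12
Tet3	6	83404686	Ctt	Ttt	L	F	3/3	0.01	-1.65
Aak1	6	86965533	aAt	aGt	N	S	14/21	0.09	-2.66
Gfpt1	6	87053776	aCa	aTa	T	I	4/5	0	-0.48
D6Ertd527e	6	87111649	ACc	CTc	T	L	2/2	NA	-4.67
Chchd6	6	89467434	Cgt	Tgt	R	C	5/8	0.03	-3.51
Zfyve20	6	92199851	cGg	cAg	R	Q	7/12	0.02	-1.32
Lmod3	6	97252294	aGt	aAt	S	N	1/3	0.02	-0.55
Ttll3	6	113409684	Ggg	Agg	G	R	2/2	0.04	-1.33
Cidec	6	113433131	Cgt	Agt	R	S	3/6	0	-5.85
Irak2	6	113647785	Ctg	Gtg	L	V	2/12	0	-2.4
Rpl28-ps4	6	117213939	cAa	cGa	Q	R	1/1	0	-0.09
Ret	6	118179286	aCc	aTc	T	I	5/20	0	-3.05
Cacna1c	6	118602267	aCt	aAt	T	N	42/47	0.43	-2.93
Cecr5	6	120510398	Cgt	Tgt	R	C	8/8	0.04	-1.85
A2m	6	121639361	atG	atA	M	I	3/36	0.02	-0.6
A2m	6	121661523	aCg	aAg	T	K	21/36	0	-5.88
8430419L09Rik	6	135209106	tCg	tTg	S	L	2/2	NA	-6.0
8430419L09Rik	6	135209130	aTg	aCg	M	T	2/2	NA	-6.0
8430419L09Rik	6	135209172	cAg	cGg	Q	R	2/2	NA	-4.0
8430419L09Rik	6	135209250	cGg	cAg	R	Q	2/2	NA	-4.0
8430419L09Rik	6	135209265	gCc	gTc	A	V	2/2	NA	-4.0
Atf7ip	6	136561386	tCg	tTg	S	L	3/4	0.01	-0.72
Atf7ip	6	136561422	aGt	aCt	S	T	3/4	0.05	-0.12
BC049715	6	136840037	Act	Cct	T	P	1/1	0.11	-3.22
BC049715	6	136840106	Aga	Gga	R	G	1/1	0.37	-2.86
BC049715	6	136840191	aTg	aCg	M	T	1/1	0.01	-4.56
Art4	6	136857180	Ccc	Acc	P	T	1/3	0.02	-1.15
Mgp	6	136872651	aAa	aGa	K	R	4/4	0.02	-0.33
Ptpro	6	137368083	aCg	aTg	T	M	2/27	0.03	-1.93
Igbp1b	6	138658041	aCg	aTg	T	M	1/1	0.05	-1.27
Pik3c2g	6	139967890	Agt	Tgt	S	C	16/16	0.01	-2.86
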