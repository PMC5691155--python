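locus	chr	start	end	replicated	n_distinct_snps	n_significant_snps	genes	top_p
1	1	10509603	11264064	Y	2	168	DFFA	6.04E-49
2	1	24570475	25511358	Y	4	143	SYF2-RUNX3	1.28E-20
3	1	41354272	41407656	N	1	7	CITED4	5.74E-09
4	1	47917547	48002096	Y	1	26	FOXD2	6.57E-12
5	1	50019849	51742123	N	1	248	DMRTA2	6.47E-13
6	1	118536585	119857264	Y	4	268	WARS2	3.14E-19
7	1	151997199	152310892	N	1	14	RPTN-TCHH	1.08E-10
8	1	170194002	170907900	Y	2	572	PRRX1	2.78E-20
9	1	203714162	203979114	N	1	6	SOX13	8.57E-15
10	2	6089096	6573742	Y	1	16	ESPN(trans-eQTL)	8.24E-10
11	2	30585541	30632740	N	1	16	LCLAT1	7.66E-09
12	2	31490493	33520716	Y	5	207	SRD5A2	1.90E-26
13	2	60517707	60697464	N	1	12	.	8.77E-09
14	2	67675400	68172629	Y	1	54	.	7.75E-12
15	2	70196019	70558994	N	1	116	FAM136A	4.05E-08
16	2	145638766	145881714	N	1	12	.	1.90E-08
17	2	174268562	174617984	N	1	5	CDCA7	4.61E-10
18	2	176794997	177889303	Y	2	232	HOXD3	1.49E-14
19	2	219291486	219854317	Y	1	82	WNT10A	1.07E-19
20	2	222988705	223108422	N	1	23	PAX3	3.63E-10
21	2	239495665	239950595	Y	2	171	TWIST2	1.43E-39
22	3	107181737	107427969	N	1	1	BBX	1.18E-10
23	3	125899126	126278765	Y	2	26	.	4.84E-13
24	3	138648310	139032333	Y	2	59	COPB2	2.26E-21
25	3	141093285	141336557	N	1	9	ALPL(trans-eQTL)	2.75E-08
26	3	151406296	151781794	Y	2	252	AADAC	8.21E-18
27	4	81095299	81307025	Y	1	108	FGF5-PRDM8	4.60E-25
28	4	106008586	106038169	N	1	11	TET2	2.63E-09
29	4	107146797	108477318	Y	2	47	DKK2	8.10E-11
30	5	122084693	122490489	N	1	6	PPIC-PRDM6	1.44E-08
31	5	157510608	158614607	Y	1	206	EBF1-UBLCP1	2.29E-44
32	6	226393	615736	Y	1	33	IRF4	2.35E-52
33	6	8915298	10241822	Y	3	452	OFCC1	9.05E-29
34	6	44684124	45756667	N	1	1	RUNX2	3.62E-08
35	6	105957344	106256325	N	2	32	.	9.09E-14
36	6	126268105	127212478	Y	1	359	CENPW	1.66E-17
37	7	428825	574149	N	2	109	PDGFA	6.00E-20
38	7	18683672	19141259	Y	2	132	TWIST1	7.34E-63
39	7	46798132	47074382	Y	1	223	EPS15P1	1.07E-17
40	7	68566391	69822973	Y	2	531	AUTS2	2.06E-41
41	7	130742066	131010943	N	1	11	.	2.94E-08
42	8	108420980	110628938	Y	5	298	RSPO2	2.13E-22
43	8	116416322	117271922	N	2	143	TRPS1	2.71E-10
44	9	109559481	109695139	N	1	4	ZNF462	7.25E-09
45	10	62826952	62995640	N	1	18	RHOBTB1	4.59E-09
46	10	78076367	78640827	Y	1	662	C10orf11	9.31E-24
47	10	126266230	126576345	Y	1	66	METTL10-FAM53B	2.58E-17
48	11	27360070	27567092	N	1	31	LGR4	8.99E-12
49	11	44374074	44526229	Y	1	94	ALX4	2.14E-19
50	12	26356406	26458670	Y	1	22	SSPN	1.62E-16
51	12	27983266	28116111	Y	1	18	PTHLH	3.43E-09
52	12	28655747	29440112	N	1	208	FAR2	5.73E-14
53	12	130556647	130579675	Y	1	14	.	1.73E-12
54	14	30548135	30575473	N	1	2	PRKD1	3.65E-08
55	15	56926063	57873575	Y	1	95	.	1.08E-11
56	15	69964858	70048984	Y	1	93	.	4.25E-15
57	15	90466945	91088596	N	1	49	CRTC3-IQGAP1	1.90E-08
58	16	14377400	14406119	Y	1	12	.	1.42E-08
59	17	12250947	12521291	N	1	23	.	1.54E-09
60	17	43074095	44865603	Y	3	3920	WNT3-MAPT-PLEKHM1	1.49E-26
61	17	55217723	55287871	Y	1	88	MSI2	8.95E-23
62	18	9971288	10451695	N	1	1	APCDD1	7.09E-10
63	18	42437417	42838477	Y	1	160	SETBP1	8.03E-25
64	18	60924613	60943706	N	1	3	BCL2	2.35E-08
65	20	21627103	22417667	Y	3	910	PAX1	1.42E-105
66	20	39620847	40270138	Y	1	96	ZHX3-TOP1	4.04E-16
67	20	55269324	55435053	N	2	4	TFAP2C	5.40E-11
68	21	36198190	36238517	Y	1	7	RUNX1	9.94E-19
69	21	45935196	46174999	N	1	20	.	1.06E-09
70	X	8874087	8916646	Y	1	2	FAM9B	4.07E-13
71	X	55163863	67910139	Y	3	114	AR	1E-879
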