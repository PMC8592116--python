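locus	index_snps	secondary_signal	nearest_genes	nearest_suspect	gene1	score1	share1	closest1	gene2	score2	share2	closest2	gene3	score3	share3	closest3
1q21.3-a	rs61813875	0	CRCT1/LCE3E	0	HRNR	464	28	0	RPTN	285	17	0	CRNN	249	15	0
1q21.3-b	rs12730935	0	IL-6R	0	IL-6R	743	62	1	UBE2Q1	93	8	0	ADAR	61	5	0
2p13.3	rs112111458	0	CD207/VAX2	0	CD207	272	45	1	CLEC4F	62	10	0	VAX2	56	9	0
2q12.1	rs6419573/rs3917265	1	IL-18R1/IL-18RAP	0	IL-18R1	1384	39	1	IL-18RAP	1341	38	1	IL1RL1	224	6	0
2q37.1	rs1057258	0	INPP5D	0	INPP5D	296	57	1	ATG16L1	106	20	0	RN7SL32P	29	6	0
4q27	rs6827756/rs13152362	1	KIAA1109	0	KIAA1109	220	35	1	BBS12	112	18	0	TRPC3	100	16	0
5p13.2	rs10214237	0	IL-7R/CAPSL	0	IL-7R	965	65	1	SPEF2	203	14	0	UGT3A2	89	6	0
5q31.1-a	rs12188917	0	TH2LCRR	0	SLC22A5	461	35	0	IRF1	303	23	0	RAD50	122	9	0
5q31.1-b	rs4705962	1	KIF3A	0	KIF3A	249	23	1	SLC22A5	247	23	0	PDLIM4	142	13	0
6p21.32	rs4713555	0	STAT3	1	HLA-DRA	1405	30	0	HLA-DQB1	689	15	0	HLA-DRB1	566	12	1
6p21.33	rs41293864	0	MICB	0	HSPA1B	173	15	0	HCG27	165	14	0	CSNK2B	152	13	0
8q21.13	rs6473227	0	MIR5708/ZBTB10	0	ZBTB10	192	41	1	TPD52	70	15	0	PAG1	69	15	0
10p15.1	rs6602364	0	IL2RA/IL15RA	0	IL-2RA	333	45	1	RBM17	111	15	0	PFKFB3	51	7	0
10q21.2	rs2944542	0	ZNF365	0	ADO	615	61	0	ZNF365	101	10	1	EGR2	90	9	0
11p13	rs2592555/rs12295535	1	PRR5L	0	PRR5L	598	79	1	TRAF6	65	9	0	COMMD9	34	5	0
11q13.1	rs10791824	0	OVOL1	0	CTSW	336	23	0	OVOL1	236	16	1	EFEMP2	168	11	0
11q13.5	rs2212434	0	C11orf30/LRRC32	0	LRRC32	545	43	1	EMSY	521	41	1	THAP12	47	4	0
11q24.3	rs7127307	0	–/ETS1	0	ETS1	298	75	1	FLII	35	9	0	APLP2	18	5	0
12q15	rs2227483	0	IL22	0	MDM1	728	70	0	IL-22	99	10	1	IFNG	57	5	0
14q13.2	rs2038255	0	PPP2R3C	0	PPP2R3C	996	31	1	KIAA0391	814	25	0	SRP54	433	13	0
14q32.32	rs7146581	0	TRAF3	0	TRAF3	848	55	1	AMN	281	18	0	CDC42BPB	186	12	0
16p13.13	rs2041733	0	CLEC16A	0	DEXI	376	34	0	CLEC16A	364	33	1	RMI2	108	10	0
17q21.2	rs12951971	0	STAT3	0	DHX58	254	32	0	STAT3	101	13	1	RAB5C	100	13	0
17q25.3	rs11657987	0	PGS1	0	PGS1	205	46	1	DNAH17	73	16	0	SOCS3	52	12	0
19p13.2	rs2918307	0	ADAMTS10/ACTL9	0	ACTL9	115	41	1	ADAMTS10	57	20	1	MAP2K7	34	12	0
20q13.33	rs4809219	0	RTEL1/TNFRSF6B	0	STMN3	608	27	0	LIME1	473	21	0	ARFRP1	257	12	0
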