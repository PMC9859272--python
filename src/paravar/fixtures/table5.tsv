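gene	codon	ref_aa	variant	phenotype	syn	nonsyn	selection_score	window_sum	aa_conservation	gnomad_count	geno2mp_var	hpo_profiles	cadd
SOX1	126	T	T126I	Abnormality of hindbrain morphology	1	0	1	25.25	0.97	1	T126I	1	21.7
SOX2	123	D	D123G	Developmental disorder	4	0	1.25	17.5	1.00	1
SOX2	130	G	G130A	abnormalities of the central nervous system	8	0	1.25	15.25	0.99	17	G130A	1	23.3
SOX2	133	A	A133T	Anophthalmia/microphthalmia-esophageal atresia syndrome	22	0	2	11.25	0.96	8	A133T	3	23.3
SOX2	272	D	D272N	not provided	1	0	1	13.75	0.97
SOX5	135	R	R122H	Intellectual disability	10	0	1.25	23.75	0.94	1	R122H	1	35
SOX5	159	P	P146L	Thoracic aortic aneurysm	10	0	1.25	14.75	0.94	1	P146L	1	25.1
SOX5	206	I	I206V	Lamb-Shaffer syndrome	4	0	1	19.75	0.95
SOX5	228	A	A215V	Coarctation of aorta	22	0	1.5	20.5	0.95	10	A215V	1	33
SOX5	261	K	K261N	not provided	4	0	1	22.5	0.96
SOX5	266	Q	Q266H	Lamb-Shaffer syndrome	7	0	1.25	16.25	0.96
SOX5	268	Q	Q268H	Lamb-Shaffer syndrome	5	0	1	14.5	0.96
SOX6	146	E	E146K	not provided	10	0	1.5	13	0.95	2	E146D	2	20.4
SOX6	209	H	H209K	Multiple neurological	16	0	2	22.25	0.97
SOX6	214	K	K214Q	Hypoplastic left-heart syndrome	8	0	1.25	23.5	0.97	4	K214Q	2	22
SOX6	252	N	N252K	not provided	3	0	1	18.25	0.97
SOX6	264	M	M264I	myopathy	0	0	1	17.25	0.96	5	M264I	1	22.1
SOX6	277	R	R277W	not provided	7	0	1	19.75	0.97	14
SOX6	280	A	A280E	Aplasia/Hypoplasia affecting the eye	4	0	1	18.75	0.97	1	A280E	2	23.1
SOX6	281	A	A281T	not provided	8	0	1.25	19	0.97	1
SOX6	291	F	F291L	cardiovascular system	7	0	1.25	17	0.97	5	F291L	1	22.4
SOX6	310	S	S310T	Microcephaly	5	0	1	13.25	0.97	56	S310T	2	21.6
SOX6	312	M	M312V	not provided	0	0	1	13.75	0.95
SOX6	371	A	A330P	Aplasia/Hypoplasia affecting the eye	10	0	1.25	14	0.99	1	A330P	1	23.9
SOX6	512	R	R485Q	Abnormality of nervous system	12	0	1.25	17	0.99	2	R485Q	1	28.5
SOX6	572	R	R545Q	Intellectual disability	9	0	1.25	15	0.99	6	R545Q	1	32
SOX6	618	E	E591K	Intellectual disability	10	0	1.5	20.25	0.98	1	E591K	1	35
SOX7	128	R	R128C	abnormality of the central nervous system	30	0	1.5	12	0.99	4	R128C	1	21.8
SOX7	329	R	R329H	Nephrotic syndrome	19	0	1.25	15.25	1.00	3	R329H	1	25.3
SOX7	379	A	A379V	Abnormality of the eye (x4)	25	0	1.25	21	0.99	195	A379V	9	29
SOX8	263	N	N263I	Abnormality of the nervous system (x2)	17	0	1.25	13.25	0.99	45	N263I	6	24.1
SOX9	73	I	I73T	Campomelic dysplasia	2	0	1	14.25	0.97
SOX9	76	A	A76E	Inborn genetic diseases	32	0	2	17	0.97
SOX9	81	L	L81V	Campomelic dysplasia	20	0	1.25	18.25	0.97	1
SOX9	83	G	G83R	Inborn genetic diseases	10	0	1	20.25	0.97
SOX10	68	F	F68L	PCWH syndrome	4	0	1	12.5	0.96	1
SOX10	75	A	A75V	Malformation of the heart and great vessels (x2)	20	0	1.5	17.25	0.96		A75V	2	34
SOX10	92	V	V92M/L	PCWH syndrome	7	0	1	17.5	0.97	46	V92L	4	24.1
SOX10	179	K	K179N	not provided	3	0	1	19.25	1.00
SOX10	181	G	G181R	not provided	9	0	1	17.5	0.98	1
SOX10	216	H	H216Q	not provided	4	0	1	13	0.74
SOX10	240	T	T240P	Waardenburg syndrome type 4C	12	0	1.25	16.25	1.00
SOX10	278	I	I278V	Aganglionic megacolon	15	0	1.5	12.75	1.00	25
SOX10	428	M	M428I	Abnormality of limb bone	0	0	1	15.75	0.99	14	M428I	2	22.7
SOX10	433	R	R433Q	not provided	6	0	1	19.5	0.99	2
SOX11	417	C	C417W	not provided	4	0	1	17.25	0.95
SOX13	171	S	S171L	Abnormality of the ear	36	2	1	13	0.99	2	S171L	1	26.3
SOX13	192	R	R192Q	Multiple	15	0	1.25	22.25	0.99	4	R192Q	5	34
SOX13	210	H	H210R	Neural Atrophy/Degeneration	13	0	1.5	21.25	0.98	4	H210R	4	26.7
SOX13	507	R	R507Q	Muscular dystrophy	16	0	1.25	19.5	0.96	3	R507Q	2	34
SOX14	88	K	K88R	Abnormality of the cardiovascular system (x9)	4	0	1	23	0.95	52	K88R	8	25.8
SOX14	187	T	T187K	Hypoplastic left-heart syndrome	5	0	1	21	1.00	1	T187K	2	25.4
SOX18	326	E	E326V	Skeletal muscle atrophy	1	0	1	10.25	1.00		E326V	1	21.4
SOX18	331	L	L331F	HLTS	9	0	1	11	1.00
SOX18	369	L	L369V	not provided	19	0	1.25	16	1.00	1
SOX18	375	A	A375T	Nephrotic syndrome	35	0	2	13.25	0.99		A375T	1	20.4
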