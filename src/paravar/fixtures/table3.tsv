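uniprot_pos	bowles_pos	aa_used	aa_set	cons_mean	cons_sd	publications	unique_clinvar	gnomad_count	hpo_profiles	gene	variant	syn	nonsyn	conservation_score
-1	2	3	RHK	0.93	0.08		2	6	1	SOX4	H58P	4	0	1
1	3	2	VI	0.92	0.09	3	3	6	3	SOX4	I59S	7	0	1.25
1	3	2	VI	0.92	0.09	3	3	6	3	SOX9	V105F	11	0	1
2	4	2	KR	0.94	0.07		3	3	1	SOX3	K140R	10	0	2
2	4	2	KR	0.94	0.07		3	3	1	SOX9	K106E	9	0	1.25
2	4	2	KR	0.94	0.07		3	3	1	SOX10	K105Q	4	0	1
3	5	1	R	0.94	0.07	2	10	2	0	SOX4	R61Q	22	0	1.5
3	5	1	R	0.94	0.07	2	10	2	0	SOX5	R558H	10	0	1.25
3	5	1	R	0.94	0.07	2	10	2	0	SOX6	R623Q	9	0	1.25
3	5	1	R	0.94	0.07	2	10	2	0	SOX10	R106G	15	0	1.25
5	7	1	M	0.95	0.05	2	4	21	2	SOX6	M625T	0	0	1
5	7	1	M	0.95	0.05	2	4	21	2	SOX10	M108T	0	0	1
6	8	1	N	0.95	0.05		3	1152	1	SOX5	N561H	10	0	1.5
6	8	1	N	0.95	0.05		3	1152	1	SOX10	N109S	16	0	2
7	9	1	A	0.95	0.05		4	2	0	SRY	A66P	6	0	1.5
7	9	1	A	0.95	0.05		4	2	0	SOX4	A65T	17	0	1.25
7	9	1	A	0.95	0.05		4	2	0	SOX9	A111T	13	0	1
7	9	1	A	0.95	0.05		4	2	0	SOX10	A110V	2	0	1
9	11	2	MI	0.95	0.04	4	9	4	0	SOX9	M113V/I	0	0	1
9	11	2	MI	0.95	0.04	4	9	4	0	SOX10	M112V/R/T/I	0	0	1
10	12	1	V	0.95	0.04		1	5	0	SOX9	V114L	12	0	1
11	13	1	W	0.95	0.06	1	4	1	0	SOX11	W59R	0	0	1
11	13	1	W	0.95	0.06	1	4	1	0	SOX9	W115R	0	0	1
11	13	1	W	0.95	0.06	1	4	1	0	SOX6	W631C	0	0	1
12	14	2	SA	0.96	0.03		5	2	0	SOX11	S60P	20	0	1.5
12	14	2	SA	0.96	0.03		5	2	0	SOX9	A116V	23	0	1.5
15	17	4	QEAH	0.95	0.04	1	1	29	2	SOX9	A119E	15	0	1.25
16	18	1	R	0.95	0.04		10	4	0	SOX2	R56G/W	13	0	1.25
16	18	1	R	0.95	0.04		10	4	0	SOX9	R120G/L	20	0	1.25
16	18	1	R	0.95	0.04		10	4	0	SOX11	R64C/G/H	16	0	1.25
16	18	1	R	0.95	0.04		10	4	0	SOX10	R119L	8	0	1
16	18	1	R	0.95	0.04		10	4	0	SOX5	R571L/W	16	0	1.25
19	21	3	MIL	0.93	0.08	1	2	6	0	SOX4	I77V	12	0	1.5
19	21	3	MIL	0.93	0.08	1	2	6	0	SOX10	L122V	20	0	1.25
20	22	3	AML	0.94	0.09	1	4	9	0	SOX9	A124P	35	1	1
20	22	3	AML	0.94	0.09	1	4	9	0	SOX10	A123P	15	0	1.25
24	26	1	P	0.94	0.10		1	14	6	SRY	P83H	2	0	1.25
26	28	3	MLA	0.94	0.09		3	10	2	SOX10	L129P	11	0	1
28	30	1	N	0.94	0.09	2	3	16	0	SOX11	N76D	4	0	1
28	30	1	N	0.94	0.09	2	3	16	0	SOX5	N583S	9	0	1.25
28	30	1	N	0.94	0.09	2	3	16	0	SOX17	N95S	9	0	1.5
29	31	2	SA	0.94	0.08		2	3	0	SOX10	A132G/V	19	0	1.5
31	33	2	IL	0.94	0.10	3	3	4	2	SOX11	I79L	12	0	1.5
31	33	2	IL	0.94	0.10	3	3	4	2	SOX10	L134P	4	0	1
32	34	1	S	0.94	0.11	1	7	3	0	SOX11	S80F/C	2	0	1
32	34	1	S	0.94	0.11	1	7	3	0	SOX5	S587C	1	0	1
32	34	1	S	0.94	0.11	1	7	3	0	SOX10	S135R/G/T	5	0	1
33	35	2	KV	0.93	0.10	1	1	0	0	SOX5	K588N	5	0	1
34	36	5	RQITM	0.95	0.06		2	21	9	SOX2	R74P	16	0	1.5
34	36	5	RQITM	0.95	0.06		2	21	9	SOX9	T138K	27	0	1.5
35	37	1	L	0.95	0.07	1	1	1	1	SOX4	L93Q	11	0	1
36	38	1	G	0.95	0.07	2	6	3	2	SOX2	G76D	8	0	1.25
36	38	1	G	0.95	0.07	2	6	3	2	SRY	G95R/E	2	0	1.25
36	38	1	G	0.95	0.07	2	6	3	2	SOX9	G140D	14	0	1
36	38	1	G	0.95	0.07	2	6	3	2	SOX10	G139C/D	10	0	1
38	40	7	EDQRLSA	0.93	0.10		2	23	3	SOX10	L141P	11	0	1
39	41	1	W	0.96	0.06	1	7	1	0	SOX4	W97G	0	0	1
39	41	1	W	0.96	0.06	1	7	1	0	SOX6	W659R	0	0	1
39	41	1	W	0.96	0.06	1	7	1	0	SOX10	W142R/S/C	0	0	1
47	49	1	K	0.96	0.06	2	3	24	0	SRY	K106I	1	0	1.25
47	49	1	K	0.96	0.06	2	3	24	0	SOX10	K150E	5	0	1
47	49	1	K	0.96	0.06	2	3	24	0	SOX4	K105N	1	0	1
48	50	5	RWIQK	0.96	0.05	1	2	12	0	SOX10	R151P	15	0	1.25
50	52	2	FY	0.96	0.02	2	5	11	0	SRY	F109S	2	0	1.25
50	52	2	FY	0.96	0.02	2	5	11	0	SOX9	F154L	14	0	1.5
50	52	2	FY	0.96	0.02	2	5	11	0	SOX10	F153I	13	0	1.5
52	54	4	DQRE	0.92	0.13		2	11	1	SOX10	E155K	6	0	1
53	55	1	E	0.97	0.02		1	285	16	SOX18	E137K	10	0	2
54	56	2	AQ	0.97	0.03	3	6	9	1	SRY	A113T	5	0	1.5
54	56	2	AQ	0.97	0.03	3	6	9	1	SOX11	A102V	16	0	1.25
54	56	2	AQ	0.97	0.03	3	6	9	1	SOX10	A157V	28	0	2
54	56	2	AQ	0.97	0.03	3	6	9	1	SOX4	A112P	11	0	1.25
55	57	4	KQEA	0.96	0.04		2	9	1	SOX17	E122D	3	0	1
56	58	2	RK	0.96	0.07		4	14	4	SOX2	R96P	6	0	1
56	58	2	RK	0.96	0.07		4	14	4	SOX9	R160P	19	0	1.25
56	58	2	RK	0.96	0.07		4	14	4	SOX5	R611G	22	0	1.5
56	58	2	RK	0.96	0.07		4	14	4	SOX6	R676Q	13	0	1.25
57	59	2	LI	0.97	0.01		2	0	0	SOX2	L97P	5	0	1
57	59	2	LI	0.97	0.01		2	0	0	SOX10	L160P	12	0	1
58	60	4	RQSK	0.97	0.02	1	3	76	2	SOX10	R161C/H	15	0	1.25
58	60	4	RQSK	0.97	0.02	1	3	76	2	SOX17	R125S	18	0	1.25
61	63	1	H	0.95	0.10	2	4	3	0	SOX2	H101R	1	0	1
61	63	1	H	0.95	0.10	2	4	3	0	SOX9	H165Y/R	7	0	1.25
61	63	1	H	0.95	0.10	2	4	3	0	SOX10	H164P	5	0	1
63	65	5	KEAQR	0.94	0.10		1	26	2	SOX10	K166E	11	0	1.25
65	67	3	HYF	0.95	0.06		2	4	3	SOX11	Y113C	16	1	1
68	70	2	YW	0.95	0.08	3	6	4	0	SOX11	Y116C	3	0	1
68	70	2	YW	0.95	0.08	3	6	4	0	SOX17	Y135C	3	0	1
70	72	1	Y	0.95	0.11		4	0	0	SOX4	Y128H	2	0	1
71	73	3	RKQ	0.95	0.08	1	3	11	4	SOX10	Q174P	8	0	1.25
72	74	1	P	0.93	0.13	4	9	4	0	SOX2	P112T/A	11	0	1.25
72	74	1	P	0.93	0.13	4	9	4	0	SOX11	P120L	13	0	1.25
72	74	1	P	0.93	0.13	4	9	4	0	SOX9	P176T/S/L/R	35	1	1
72	74	1	P	0.93	0.13	4	9	4	0	SOX6	P692S	11	0	1.25
72	74	1	P	0.93	0.13	4	9	4	0	SOX10	P175S	17	0	1.25
73	75	1	R	0.91	0.14		3	25	4	SOX2	R113W	4	0	1
74	76	3	RKP	0.92	0.13	1	3	6	0	SOX10	R177Q	25	0	1.5
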