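hmg_box_pos	protein_pos	ref_aa	alt_aa	gene	disease	reference	url
-	3	S	L	SRY	SRXY1	Gimelli et al., 2007	http://www.ncbi.nlm.nih.gov/pubmed/17063144
-	18	S	N	SRY	Partial SRXY1	Domenice et al., 1998	http://www.ncbi.nlm.nih.gov/pubmed/9521592
-	18	S	N	SRY	Tuner Syndrome	Canto et al., 2000	http://www.ncbi.nlm.nih.gov/pubmed/10843173
-	59	R	G	SRY	45,X/46,X psu dic (Y)	Fernandez et al., 2001	http://www.ncbi.nlm.nih.gov/pubmed/12215836
1/3	60	V	L	SRY	SRXY1	Vilain et al., 1992	http://www.ncbi.nlm.nih.gov/pubmed/1570829
1/3	60	V	L	SRY	SRXY1	Berta et al., 1990	http://www.ncbi.nlm.nih.gov/pubmed/2247149
1/3	60	V	A	SRY	SRXY1	Hiort et al., 1995	http://www.ncbi.nlm.nih.gov/pubmed/7776083
3/5	106	R	W	SOX10	WS4C	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
3/5	62	R	G	SRY	SRXY1	Affara et al., 1993	http://www.ncbi.nlm.nih.gov/pubmed/8353496
4/6	108	P	L	SOX9	CMD1	Meyer et al., 1997	http://www.ncbi.nlm.nih.gov/pubmed/9002675
5/7	64	M	I	SRY	SRXY1	Berta et al., 1990	http://www.ncbi.nlm.nih.gov/pubmed/2247149
5/7	64	M	R	SRY	SRXY1	Scherer et al., 1998	http://www.ncbi.nlm.nih.gov/pubmed/9678356
8/10	67	F	V	SRY	SRXY1	Scherer et al., 1998	http://www.ncbi.nlm.nih.gov/pubmed/9678356
8/10	112	F	L	SOX9	CMD1	Kwok et al., 1995	http://www.ncbi.nlm.nih.gov/pubmed/7485151
8/10	112	F	S	SOX9	CMD1	Goji et al., 1998	http://www.ncbi.nlm.nih.gov/pubmed/9452059
9/11	68	I	T	SRY	SRXY1	Haqq et al., 1994	http://www.ncbi.nlm.nih.gov/pubmed/7985018
9/11	113	M	T	SOX9	CMD1	Wada et al., 2009	http://www.ncbi.nlm.nih.gov/pubmed/19921652
9/11	113	M	V	SOX9	CMD1	Staffler et al., 2010	http://www.ncbi.nlm.nih.gov/pubmed/20513132
9/11	112	M	I	SOX10	WS2E/PCWH	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
11/13	95	W	R	SOX18	HLTS	Irrthum et al., 2003	http://www.ncbi.nlm.nih.gov/pubmed/12740761
15/17	119	A	V	SOX9	CMD1	Kwok et al., 1995	http://www.ncbi.nlm.nih.gov/pubmed/7485151
17/19	76	R	S	SRY	SRXY1	Imai et al., 1999	http://www.ncbi.nlm.nih.gov/pubmed/10670762
19/21	78	M	T	SRY	SRXY1	Affara et al., 1993	http://www.ncbi.nlm.nih.gov/pubmed/8353496
20/22	104	A	P	SOX18	HLTS	Irrthum et al., 2003	http://www.ncbi.nlm.nih.gov/pubmed/12740761
28/30	87	N	Y	SRY	SRXY1	Okuhara et al., 2000	http://www.ncbi.nlm.nih.gov/pubmed/10721678
28/30	131	N	H	SOX10	PCWH	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
30/32	89	E	K	SRY	SRXY1	Cunha et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21344134
31/33	90	I	M	SRY	SRXY1	Hawkins et al., 1992a	http://www.ncbi.nlm.nih.gov/pubmed/1415266
31/33	90	I	M	SRY	SRXY1	Dork et al., 1998	http://www.ncbi.nlm.nih.gov/pubmed/9450909
31/33	90	I	M	SRY	SRXY1	Maier et al., 2003	http://www.ncbi.nlm.nih.gov/pubmed/12793612
32/34	91	S	G	SRY	SRXY1	Schmitt-Ney et al., 1995	http://www.ncbi.nlm.nih.gov/pubmed/7717397
33/35	92	K	M	SRY	SRXY1	Shahid et al., 2009	http://www.uniprot.org/uniprot/D0VTX3
35/37	94	L	W	SRY	Tuner Syndrome	Shahid et al., 2009	http://www.uniprot.org/uniprot/D0VTX0
36/38	95	G	E	SRY	SRXY1	Schaeffler et al., 2000	http://www.ncbi.nlm.nih.gov/pubmed/10852465
36/38	95	G	R	SRY	SRXY1	Hawkins et al., 1992b	http://www.ncbi.nlm.nih.gov/pubmed/1339396
39/41	143	W	R	SOX9	CMD1	Meyer et al., 1997	http://www.ncbi.nlm.nih.gov/pubmed/9002675
42/44	101	L	H	SRY	SRXY1	Braun et al., 1993	http://www.ncbi.nlm.nih.gov/pubmed/8447323
42/44	145	L	P	SOX10	WS4C	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
47/49	106	K	I	SRY	SRXY1	Hawkins et al., 1992a	http://www.ncbi.nlm.nih.gov/pubmed/1415266
47/49	150	K	N	SOX10	PCWH	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
48/50	152	R	P	SOX9	CMD1	Meyer et al., 1997	http://www.ncbi.nlm.nih.gov/pubmed/9002675
49/51	108	P	R	SRY	SRXY1	Jakubiczka et al., 1999	http://onlinelibrary.wiley.com/doi/10.1002/(SICI)1098-1004(1999)13:1%3C85::AID-HUMU16%3E3.0.CO;2-O/abstract
50/52	109	F	S	SRY	SRXY1	Jaeger et al., 1992	http://www.ncbi.nlm.nih.gov/pubmed/1483689
50/52	154	F	L	SOX9	CMD1	Preiss et al., 2000	http://www.ncbi.nlm.nih.gov/pubmed/11323423
54/56	113	A	T	SRY	SRXY1	Zeng et al., 1993	http://www.ncbi.nlm.nih.gov/pubmed/8105086
54/56	158	A	T	SOX9	CMD1	Preiss et al., 2000	http://www.ncbi.nlm.nih.gov/pubmed/11323423
54/56	157	A	V	SOX10	WS4C	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
58/60	161	R	H	SOX10	WS2E	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
59/61	118	A	P	SRY	SRXY1	Shahid et al., 2009	http://www.uniprot.org/uniprot/D0VTX2
61/63	165	H	Y	SOX9	CMD1	McDowall et al., 1999	http://www.ncbi.nlm.nih.gov/pubmed/10446171
61/63	165	H	Q	SOX9	CMD1	Staffler et al., 2010	http://www.ncbi.nlm.nih.gov/pubmed/20513132
66/68	170	P	R	SOX9	CMD1	Meyer et al., 1997	http://www.ncbi.nlm.nih.gov/pubmed/9002675
66/68	170	P	L	SOX9	CMD1	Wada et al., 2009	http://www.ncbi.nlm.nih.gov/pubmed/19921652
66/68	125	P	L	SRY	SRXY1	Schmitt-Ney et al., 1995	http://www.ncbi.nlm.nih.gov/pubmed/7717397
68/70	127	Y	C	SRY	SRXY1	Poulat et al., 1994	http://www.ncbi.nlm.nih.gov/pubmed/8019555
68/70	127	Y	F	SRY	SRXY1	Jordan et al., 2002	http://www.ncbi.nlm.nih.gov/pubmed/12107262
68/70	127	Y	I	SRY	SRXY1	Shahid et al., 2009	http://www.uniprot.org/uniprot/D0VTX2
69/71	173	K	E	SOX9	CMD1	Thong et al., 2000	http://www.ncbi.nlm.nih.gov/pubmed/10951468
71/73	174	Q	P	SOX10	PCWH	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
72/74	131	P	R	SRY	SRXY1	Lundberg et al., 1998	http://onlinelibrary.wiley.com/doi/10.1002/humu.13801101108/abstract
72/74	175	P	A	SOX10	PCWH	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
72/74	175	P	L	SOX10	PCWH	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
72/74	175	P	R	SOX10	PCWH	Chaoui et al., 2011	http://www.ncbi.nlm.nih.gov/pubmed/21898658
74/76	133	R	W	SRY	SRXY1	Affara et al., 1993	http://www.ncbi.nlm.nih.gov/pubmed/8353496
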