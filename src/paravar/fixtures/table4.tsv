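gene	variant	hmg_pos	aa_used	cons_mean	cons_sd	genes_with_clinvar	phenotype	hpo_profiles	cadd	gnomad_count	syn	nonsyn	conservation_score
SOX1	E88A	38	7	0.93	0.10	2	Microcephaly	1	21.6	4	5	0	1.5
SOX10	H128Q	25	5	0.93	0.10	1	Abnormality of the ear	1	23.8	0	4	0	1
SOX10	L138P	35	1	0.95	0.07	1	Nephrotic syndrome	1	21.2	0	11	0	1
SOX11	G84S	36	1	0.95	0.07	4	Abnormality of the globe	1	28.5	0	13	0	1.25
SOX13	Q444E	21	6	0.92	0.09	0	Abnormality of the limb	2	28.6	1	16.5	2.5	1
SOX13	R461H	38	7	0.93	0.10	2	Hypoplastic left-heart	2	34	8	17	0	1.25
SOX13	A478E	55	4	0.96	0.04	2	Retinitis pigmentosa	1	28.5	2	24	0	1.5
SOX14	R63Q	56	2	0.96	0.07	4	Congenital diaphragmatic hernia	2	29.2	1	19	1	1
SOX14	R80Q	73	1	0.91	0.14	2	Abnormal muscle physiology (x2)	3	26	0	11	0	1.25
SOX15	R82L	34	5	0.95	0.06	2	Retinitis pigmentosa	2	36	9	7	0	1.25
SOX15	G84D	36	1	0.95	0.07	4	Tricuspid atresia	1	33	2	11	0	1.25
SOX15	R104G	56	2	0.96	0.07	4	Progressive muscle weakness	2	27.2	0	14	0	1.25
SOX17	M101V	34	5	0.95	0.06	2	Distal arthrogryposis	1	23.2	0	0	0	1
SOX17	R125S	58	4	0.97	0.02	2	Neural Atrophy/Degeneration	1	33	4	18	0	1.25
SOX18	E137K	53	1	0.97	0.02	1	Seizures (x2), DD/ID, ASD, brain morphology, heart	16	28.6	278	10	0	2
SOX18	N151S	67	3	0.95	0.05	0	abdominal organs	1	24	1	3	0	1
SOX18	R155Q	71	3	0.95	0.08	2	Malformation of the heart (x2)	3	26.6	1	15	0	1.25
SOX30	I367V	31	2	0.94	0.10	3	ASD, Cerebellar hypoplasia (x2)	2	22.5	0	3	0	1
SOX30	E399A	63	5	0.94	0.10	1	cardiovascular system	1	24.5	3	7	0	1.5
SOX6	D607E	14	5	0.91	0.13	0	Abnormality of the cerebral cortex	1	25.1	0	16	0	2
SOX6	M619T	26	3	0.94	0.09	3	Thoracic aortic aneurysm	1	21.5	0	0	0	1
SOX7	K81R	37	6	0.92	0.12	0	Spontaneous abortion	2	22.2	1	12	0	1.25
SOX7	A98G	54	2	0.97	0.03	5	Abnormality of hindbrain morphology	1	27.8	1	33	0	1.5
SOX7	D108N	64	3	0.95	0.11	2	central nervous system	2	35	3	17	0	1.5
SOX8	R159G	58	4	0.97	0.02	2	Intellectual disability, microcephaly (x2)	1	20.8	1	40	0	1.5
SOX8	K163R	62	4	0.96	0.02	0	Nephrotic syndrome	1	35	5	10	0	1.25
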