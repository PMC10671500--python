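id	species	length	signal_peptide	pi	mw_kda	chromosome	gene_group	subgroup	p1	p1p	target	inhibitory	stage_group	tissue_group
CpSPN1	C. pomonella	391	1-18	5.30	43.132	5	A	A2	Y	L	C	Y	I	II
CpSPN2	C. pomonella	397	1-20	4.88	43.697	1	A	A1	M	C	E	Y	II	III
CpSPN3	C. pomonella	456	1-17	5.48	50.788	3	B	B	K	F	T	Y	I	III
CpSPN4	C. pomonella	416	1-17	5.97	46.694	2	C	C2	R	I	T	Y	II	III
CpSPN5	C. pomonella	395	1-15	5.50	44.324	23	C	C1	R	F	T	Y	IV	I
CpSPN6	C. pomonella	439	1-17	5.50	49.838	1	D	D	R	S	T	Y	II	III
CpSPN7	C. pomonella	373	1-15	5.13	42.098	2	C	C4	R	F	T	Y	IV	I
CpSPN8	C. pomonella	413	1-17	6.28	47.338	19	C	C2	A	N	E	Y	IV	I
CpSPN9	C. pomonella	382	1-17	5.06	43.463	2	C	C3	R	R	T	Y	I	III
CpSPN10	C. pomonella	518	1-16	5.55	58.325	3	E	E	-	-	-	N	II	III
CpSPN11	C. pomonella	436	NO	6.28	48.631	3	F	F	L	I	C	Y	II	III
CpSPN12	C. pomonella	570	1-18	9.04	63.316	3	G	G	L	S	C	Y	II	III
CpSPN13	C. pomonella	432	1-19	5.30	49.080	3	F	F	R	T	T	Y	IV	III
CpSPN14	C. pomonella	390	1-16	9.11	44.298	2	C	C3	V	E	E	Y	IV	III
CpSPN15	C. pomonella	371	NO	5.96	41.940	22	A	A1	I	C	C	Y	III	III
CpSPN16	C. pomonella	394	1-15	6.55	43.996	2	C	C1	R	I	T	Y	II	III
CpSPN17	C. pomonella	418	NO	6.47	46.646	15	A	A1	Y	Q	C	Y	III	II
CpSPN18	C. pomonella	348	NO	5.70	39.096	15	A	A1	L	C	C	Y	III	III
CpSPN19	C. pomonella	391	NO	6.98	43.900	15	A	A1	L	C	C	Y	III	III
CpSPN20	C. pomonella	366	NO	5.64	41.271	1	E	E	-	-	-	N	IV	I
CpSPN21	C. pomonella	383	NO	5.42	43.117	15	A	A1	R	C	T	Y	III	II
CpSPN22	C. pomonella	276	NO	5.41	31.103	5	A	A2	-	-	-	N	III	I
CpSPN23	C. pomonella	345	NO	7.72	38.892	15	A	A1	Y	Q	C	Y	III	II
CpSPN24	C. pomonella	465	NO	5.68	51.965	22	A	A1	M	P	E	Y	III	II
CpSPN25	C. pomonella	814	NO	8.40	89.394	5	A	A2	V	G	E	Y	III	I
CpSPN26	C. pomonella	1405	NO	5.49	155.10	16	E	E	-	-	-	N	IV	I
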