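patient_id	total_seq_mb	read_length_bp	median_fold_cvg	n_total_var	n_cds_var	n_filtered_var	n_prioritized_var	n_tested	n_validated	mutation_label	mut_cvg	mut_read_pct	cosegregate_family	evidence_category
1	47	453	21.3	1206	114	51	8	2	2	p.C2ORF71-R571_P576del;p.FSCN2-P231S	38;25	55.3;44	M het norm;F het norm	digenic_candidate
2	47.6	433	20.9	1217	98	44	7	2	2	p.PDE6B-H337R;p.OTX2-G222R	21;52	100;48	?;?	family_unavailable
3	42.2	416	17.0	1085	78	39	6	1	1	p.CLRN1-P134L	19	68.4	?	single_het_recessive
4	44.6	395	21.6	1173	95	42	5	3	3	p.RHO-Y191C	39	38.5	yes	cosegregates
5	24.4	429	13.8	894	104	45	1	1	1	p.TULP1-F529_A530dup	6	100	yes	cosegregates
6	31.7	422	16.2	1039	85	47	1	1	1	p.RHO-R252P	22	54.5	?	reported_dominant_unconfirmed
7	20.1	281	13.3	789	77	38	4	2	2	p.SAG-E11K;p.IMPG2-G684R	30;34	56.7;38.2	no;no	non_segregating
8	13.9	445	9.1	736	70	33	2	1	1	p.RP2-D161Y	22	45.5	yes	cosegregates
9	29	297	17.3	832	80	39	9	1	1	g.ABCA4-ex45-47del	0	0	yes	cosegregates
10	37.3	443	16.7	1247	93	46	3	3	3	p.PROM1-R373C	32	50	yes	cosegregates
11	50.2	440	21.5	1151	92	46	2	1	1	p.RP2-E20X	28	67.8	yes	cosegregates
12	49.1	394	23.8	1116	94	39	9	4	4	p.CNGB1-R765C	30	100	yes	cosegregates
13	33	436	14.6	1017	85	33	3	2	2	p.GUCY2D-V887G	18	94.4	yes	cosegregates
14	32.6	443	15.3	1205	93	42	3	1	1	p.CRX-Q105X	17	58.8	M het norm	healthy_carrier_relative
15	32.7	442	14.2	1026	86	40	3	1	1	p.USH2A-P2630R	25	40	no	non_segregating
16	69.4	434	28.4	1246	87	41	1	1	1	p.PRPF31-E183_ins33bp	74	40	yes	cosegregates
17	16.7	452	9.8	861	82	43	2	2	2	p.PRPH2-L39P	18	50	yes	cosegregates
18	39.6	429	17.2	1826	85	35	3	1	1	.	.	.	.	none_found
19	66.5	449	26.4	1298	103	45	5	2	2	p.PRPH2-S217_dup16bp	71	39.4	yes	cosegregates
20	47.1	358	19.8	1171	91	47	3	2	1	p.C2ORF71-L889P	23	39.1	?	family_unavailable
21	47	363	17.3	1197	102	48	3	1	0	.	.	.	.	none_found
22	36.6	354	14.7	1072	86	45	2	2	1	p.EYS-D2930G	38	60.5	?	single_het_recessive
23	53.3	393	22.4	1164	92	40	7	5	5	p.PRPF8-E2331X	38	44.7	yes	cosegregates
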