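gene_symbol	alias	chrom	start	end	strand	n_exons	pathology
ABCA4	RP19, STGD1, CORD3, and ARMD2	1	94458391	94586688	-	50	ADRP, ARRP, ARCRD, and ARMD
AIPL1	LCA4	17	6327057	6338519	-	6	ARLCA, ADCRD
BEST1	RP50, BMD, and VMD2	11	61717293	61732987	+	11	ADRP, ARRP, and ADMD
C2ORF71	RP54	2	29284556	29297127	-	2	ARRP
CA4	RP17	17	58227302	58236902	+	8	ADRP
CABP4	CSNB2B	11	67219877	67226699	+	7	ARLCA, ARCSNB
CEP290	LCA10, BBS14, and NPHP6	12	88442794	88535993	-	53	ARLCA, ARBBS
CERKL	RP26	2	182401403	182545392	-	14	ARRP, ARCRD
CLRN1	RP61, USH3A	3	150643950	150690786	-	3	ARRP
CNGA1	RP49	4	47937994	48018689	-	13	ARRP
CNGA2	.	X	150906923	150913776	+	6	.
CNGB1	RP45	16	57917847	58005020	-	33	ARRP
CRB1	LCA8, RP12	1	197170592	197447585	+	12	ARRP, ARLCA
CRX	LCA7, CORD2	19	48325097	48364769	+	4	ADRP, ADLCA, ARLCA, and ADCRD
DHDDS	RP59	1	26758773	26797785	+	9	ARRP
EYS	RP25	6	64429876	66417118	-	43	ARRP
FAM161A	RP28	2	62051989	62081278	-	6	ARRP
FSCN2	RP30	17	79495422	79504156	+	5	ADRP, ADMD
GUCA1B	RP48, GCAP2	6	42152139	42162694	-	4	ADRP, ADMD
GUCY2D	LCA1, CORD6	17	7905988	7923658	+	20	ARLCA, ADCRD
IMPDH1	LCA11, RP10	7	128032331	128050306	-	17	ADRP, ADLCA
IMPG2	RP56, sparcan	3	100945570	101039404	-	20	ARRP
IQCB1	NPHP5	3	121488610	121553926	-	15	ARLCA
KLHL7	RP42	7	23145353	23215040	+	12	ADRP
LCA5	Lebercilin	6	80194708	80247175	-	8	ARLCA
LPCAT1	AYTL2	5	1456595	1524092	-	14	ARLCA
LRAT	LCA14	4	155548097	155674270	+	4	ARRP, ARLCA
MERTK	RP38	2	112656056	112787138	+	19	ARRP
NR2E3	RP37, PNR	15	72084977	72110559	+	8	ADRP, ARRP, and ARESCS
NRL	RP27	14	24549316	24584223	-	3	ADRP, ARRP, and ARESCS
OFD1	RP23	X	13752832	13787480	+	23	XRP
OTX2	.	14	57267426	57277197	-	5	ADLCA
PDE6A	RP43	5	149237519	149324356	-	22	ARRP
PDE6B	RP40, CSNBAD2	4	619373	664571	+	23	ARRP, ADCSNB
PDE6G	RP57	17	79617489	79623607	-	4	ARRP
PRCD	RP36	17	74523871	74541458	+	5	ARRP
PROM1	RP41, STGD4, CORD12, and MCDR2	4	15964699	16086001	-	28	ARRP, ADCRD, and ADMD
PRPF3	RP18	1	150293925	150325671	+	16	ADRP
PRPF6	RP60	20	62612488	62664453	+	21	ADRP
PRPF8	RP13	17	1553923	1588154	-	43	ADRP
PRPF31	RP11	19	54618837	54635140	+	14	ADRP
PRPH2	RDS, RP7	6	42664340	42690312	-	3	ADRP, ADMD, ADCRD, and digenic
RBP3	IRBP	10	48381487	48390991	-	4	ARRP
RDH12	LCA13, RP53	14	68168603	68201169	+	8	ADRP, ARLCA
RGR	RP44	10	86004809	86019716	+	7	ADRP, ARRP, and ADCA
RHO	RP4, CSNBAD1	3	129247483	129254012	+	5	ADRP, ARRP, and ADCSNB
RLBP1	CRALBP	15	89753098	89764922	-	9	ARRP
ROM1	.	11	62379194	62382592	+	3	ADRP, digenic
RP1	.	8	55471729	55682531	+	4	ADRP, ARRP
RP2	.	X	46696375	46741793	+	5	XRP
RP9	PAP1	7	33134409	33149013	-	7	ADRP
RPE65	LCA2, RP20	1	68894505	68915642	-	14	ARRP, ARLCA
RPGR	RP3, CORDX1	X	38128424	38186817	-	19	XRP, XCRD, XMD
RPGRIP1	LCA6, CORD13	14	21756098	21819460	+	24	ARLCA, ARCRD
SAG	RP47, Arrestin	2	234216309	234255701	+	16	ARRP, ARCSNB
SEMA4A	RP35, CORD10	1	156117157	156147543	+	16	ADRP, ARRP, and ADCRD
SNRNP200	RP33	2	96940074	96971297	-	45	ADRP
SPATA7	LCA3	14	88851268	88936694	+	12	ARLCA
TOPORS	RP31	9	32540542	32552551	-	3	ADRP
TUB	.	11	8040791	8127659	+	13	.
TULP1	LCA15, RP14	6	35465651	35480715	-	15	ARRP, ARLCA
USH2A	RP39	1	215796236	216596738	-	73	ARRP
ZNF513	RP58	2	27600098	27603657	-	4	ARRP
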