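# Validated fusion transcripts in four breast cancer cell lines, transcribed
# from the published report of the RNA-seq study this pipeline models.
# Columns: sample, 5' partner gene and chromosome, 3' partner gene and
# chromosome, supporting paired-end read count, junction-spanning read count,
# predicted frame status, and high-level amplification status.
sample	five_gene	five_chrom	three_gene	three_chrom	n_pairs	n_junction_reads	in_frame	amplified	rearrangement_validated
BT-474	ACACA	17	STAC2	17	57	72	Yes	Yes	Yes
BT-474	RPS6KB1	17	SNF8	17	43	68	Yes	Yes	Yes
BT-474	VAPB	20	IKZF3	17	41	26	Yes	Yes	Yes
BT-474	ZMYND8	20	CEP250	20	35	14	No	Yes	Yes
BT-474	RAB22A	20	MYO9B	19	9	12	No	Yes	Yes
BT-474	SKA2	17	MYO19	17	8	7	Yes	Yes	Yes
BT-474	DIDO1	20	KIAA0406	20	8	1	Yes	No
BT-474	STARD3	17	DOK5	20	4	6	Yes	Yes	Yes
BT-474	LAMP1	13	MCF2L	13	5	3	No	No	Yes
BT-474	GLB1	3	CMTM7	3	6	2	Yes	No	Yes
BT-474	CPNE1	20	PI3	20	4	2	No	Yes	Yes
SK-BR-3	TATDN1	8	GSDMB	17	28	447	Yes	Yes	Yes
SK-BR-3	CSE1L	20	ENSG00000236127	20	10	20	Yes	Yes
SK-BR-3	RARA	17	PKIA	8	13	10	Yes	Yes	Yes
SK-BR-3	ANKHD1	5	PCDH1	5	12	6	Yes	No	Yes
SK-BR-3	CCDC85C	14	SETD3	14	6	6	Yes	No	Yes
SK-BR-3	SUMF1	3	LRRFIP2	3	14	5	Yes	No
SK-BR-3	WDR67	8	ZNF704	8	3	3	Yes	Yes	Yes
SK-BR-3	CYTH1	17	EIF3H	8	38	2	Yes	Yes	Yes
SK-BR-3	DHX35	20	ITCH	20	3	2	Yes	No	Yes
SK-BR-3	NFS1	20	PREX1	20	5	9	Yes	Yes
KPL-4	BSG	19	NFIX	19	22	14	Yes	No	Yes
KPL-4	PPP1R12A	12	SEPT10	2	2	6	Yes	No	Yes
KPL-4	NOTCH1	9	NUP214	9	4	6	Yes	No	Yes
MCF-7	BCAS4	20	BCAS3	17	133	142	Yes	Yes	Previously reported
MCF-7	ARFGEF2	20	SULF2	20	17	25	Yes	Yes	Previously reported
MCF-7	RPS6KB1	17	TMEM49	17	2	7	Yes	Yes	Previously reported
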