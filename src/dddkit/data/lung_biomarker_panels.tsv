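# Packaged lung-cancer biomarker panel fixture: 38 genes in four panels.
# Frequencies and fold changes are stored verbatim as printed, including the
# exclusive "+"/"-" markers for genes observed in only one pool.
# DDD1: pool A = normal lung tissues (test pool), pool B = other normal tissues.
# DDD2: pool A = normal lung tissues, pool B = lung cancer tissues (test pool).
panel	cluster	biomarker_class	gene_symbol	ddd1_freq_a	ddd1_freq_b	ddd1_fold	ddd2_freq_a	ddd2_freq_b	ddd2_fold
1	4	metastasis diagnostic	UCHL1	0	0.0002	-	0	0.0011	+
1	4	metastasis diagnostic	LTF	0.0224	0.0018	+12.44	0.0224	0.0002	-112
2	5	chemotherapy/drug resistance	TUBA1B	0	0.0002	-	0	0.0013	+
2	5	chemotherapy/drug resistance	RPSA	0.0001	0.0004	-4	0.0001	0.0027	+27
2	5	chemotherapy/drug resistance	RPL9	0.0002	0.0006	-3	0.0002	0.002	+10
2	5	chemotherapy/drug resistance	TMSB4X	0.0004	0.001	-2.5	0.0004	0.0016	+4
2	5	chemotherapy/drug resistance	COPB1	0.0007	0.0002	+3.5	0.0007	0	-
2	5	chemotherapy/drug resistance	API5	0.0007	0.0003	+2.3	0.0007	0	-
2	5	chemotherapy/drug resistance	NT5C2	0.0008	0.0003	+2.6	0.0008	0	-
2	5	chemotherapy/drug resistance	CPN	0.0009	0.0001	+9	0.0009	0	-
2	5	chemotherapy/drug resistance	PRKAR1A	0.0017	0.0006	+2.83	0.0017	0	-
3	6	hypoxia related	FTL	0.0001	0.0011	-11	0.0001	0.0065	+65
3	6	hypoxia related	COL1A2	0.0001	0.0006	-6	0.0001	0.0023	+23
3	6	hypoxia related	GAPDH	0.0001	0.001	-10	0.0001	0.0011	+11
3	6	hypoxia related	IGKC	0.0002	0.0009	-4.5	0.0002	0.0016	+8
3	6	hypoxia related	ALDOA	0.0002	0.0006	-3	0.0002	0.0014	+7
3	6	hypoxia related	COL1A1	0.0001	0.0004	-4	0.0001	0.0009	+9
3	6	hypoxia related	FN1	0.0025	0.0012	+2.08	0.0025	0.0007	-3.57
3	6	hypoxia related	TGM2	0.0026	0.0008	+3.25	0.0026	0.0007	-3.71
3	6	hypoxia related	FOS	0.0015	0.0007	+2.14	0.0015	0.0002	-7.5
3	6	hypoxia related	CTNNA1	0.0034	0.0008	+4.25	0.0034	0.0003	-11.33
3	6	hypoxia related	FOSB	0.0024	0.0003	+8	0.0024	0.0002	-12
3	6	hypoxia related	APLP2	0.0109	0.0044	+2.47	0.0109	0.0008	-13.63
3	6	hypoxia related	NCOA4	0.0016	0.0005	+3.2	0.0016	0.0001	-16
3	6	hypoxia related	HIF1A	0.0011	0.0004	+2.75	0.0011	0	-
3	6	hypoxia related	AZIN1	0.001	0.0005	+2	0.001	0	-
3	6	hypoxia related	EHF	0.001	0.0001	+10	0.001	0	-
3	6	hypoxia related	TICAM2	0.001	0.0003	+3.33	0.001	0	-
3	6	hypoxia related	NAMPT	0.0008	0.0002	+4	0.0008	0	-
3	6	hypoxia related	TNFRSF1A	0.0008	0.0004	+2	0.0008	0	-
3	6	hypoxia related	DMBT1	0.0008	0.0001	+8	0.0008	0	-
3	6	hypoxia related	CSNK1A1	0.0007	0.0003	+2.33	0.0007	0	-
4	7	extracellular matrix	TFPI2	0	0.0004	-	0	0.002	+
4	7	extracellular matrix	RPL10	0.0001	0.0007	-7	0.0001	0.0014	+14
4	7	extracellular matrix	SFTPA1	0.0004	0	+	0.0001	0.0011	+11
4	7	extracellular matrix	KIAA1324	0.0013	0.0002	+6.5	0.0013	0	-
4	7	extracellular matrix	CRISP3	0.0009	0.0001	+9	0.0009	0	-
4	7	extracellular matrix	NET1	0.0007	0.0002	+3.5	0.0007	0	-
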