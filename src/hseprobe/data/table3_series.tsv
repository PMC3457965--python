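# Per-length design and simulation detail for the two worked probe sets
# (forward P224 C-allele probe scored at DYS390; reverse P30 C-allele
# probe scored at DYS439).  Columns: length, 5'->3' sequence, G/C%,
# simulated melting temperature (C) and free energy (kcal/mol), observed
# enrichment % with its sd and number of extractions (blank = not
# tested), and the simulated match / mismatch duplex concentrations and
# their difference in units of 1e-17 M.  Values transcribed as printed
# (decimal commas normalized); the printed delta_con occasionally differs
# from con_m - con_mm by one unit in the last digit (rounding upstream).
set_name	str_marker	length	sequence	gc_pct	tm_c	dg_kcal	hse_pct	hse_sd	n	con_m_1e17	con_mm_1e17	delta_con_1e17
P224FC	DYS390	25	TTTCAGAAATGAGTGTGACATCTTC	36	63	-10.97				297	290	7
P224FC	DYS390	24	TTCAGAAATGAGTGTGACATCTTC	38	63	-11.09				297	292	6
P224FC	DYS390	23	TCAGAAATGAGTGTGACATCTTC	39	63	-10.73	68	11	4	295	285	10
P224FC	DYS390	22	CAGAAATGAGTGTGACATCTTC	41	63	-10.80				296	287	9
P224FC	DYS390	21	AGAAATGAGTGTGACATCTTC	38	61	-9.58	85	4	3	274	233	41
P224FC	DYS390	20	GAAATGAGTGTGACATCTTC	40	59	-8.69	91	5	6	219	141	79
P224FC	DYS390	19	AAATGAGTGTGACATCTTC	37	59	-8.32	89	5	10	182	100	82
P224FC	DYS390	18	AATGAGTGTGACATCTTC	39	58	-7.95	91	7	7	141	68	73
P224FC	DYS390	17	ATGAGTGTGACATCTTC	41	57	-7.58	88	9	8	100	43	58
P224FC	DYS390	16	TGAGTGTGACATCTTC	44	54	-6.40	91	7	7	23	9	14
P224FC	DYS390	15	GAGTGTGACATCTTC	47	54	-6.56	92	4	6	29	12	17
P224FC	DYS390	14	AGTGTGACATCTTC	43	52	-6.02	86	6	6	13	5	8
P224FC	DYS390	13	GTGTGACATCTTC	46	49	-5.15	84	6	5	4	1	2
P224FC	DYS390	12	TGTGACATCTTC	42	45	-4.26	70	5	3	1	0	1
P224FC	DYS390	11	GTGACATCTTC	45	44	-4.01	79	5	3	1	0	0
P224FC	DYS390	10	TGACATCTTC	40	36	-2.85	57	6	3	0	0	0
P224FC	DYS390	9	GACATCTTC	44	35	-2.60	54	7	3	0	0	0
P224FC	DYS390	8	ACATCTTC	38	26	-2.06				0	0	0
P224FC	DYS390	6	ATCTTC	43	21	-0.93				0	0	0
P30RC	DYS439	26	TTCTATCCATCTATCATCTATTTATC	27	57	-7.43				86	48	38
P30RC	DYS439	25	TCTATCCATCTATCATCTATTTATC	28	57	-7.55	86	1	2	97	56	42
P30RC	DYS439	24	CTATCCATCTATCATCTATTTATC	29	57	-7.63	92	9	2	106	61	44
P30RC	DYS439	23	TATCCATCTATCATCTATTTATC	26	54	-6.02				13	7	7
P30RC	DYS439	22	ATCCATCTATCATCTATTTATC	27	55	-6.62	51	1	2	31	16	16
P30RC	DYS439	21	TCCATCTATCATCTATTTATC	28	53	-5.47				6	3	3
P30RC	DYS439	20	CCATCTATCATCTATTTATC	30	54	-6.04				14	7	7
P30RC	DYS439	19	CATCTATCATCTATTTATC	26	49	-4.14	46	8	2	1	0	0
P30RC	DYS439	18	ATCTATCATCTATTTATC	22	47	-3.56				0	0	0
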