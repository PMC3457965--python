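# Per-probe-set summary of the extraction experiments and simulations:
# locus (with distance to the scored STR marker in kb), set suffix, mean
# G/C% over the simulated series, distances (kb) of flanking-alignment
# hits with matching 3' end ("no" = none; "+" = further hits beyond
# 30 kb), best HSE enrichment % and the length(s) achieving it ("*" marks
# the overall best probes; "n.s." = no separation), the match-minus-
# mismatch free-energy difference ddG_M-MM (kcal/mol), the simulated best
# length(s) by maximum delta-con ("no" = no discrimination predicted),
# the printed concordance call (r = right, w = wrong prediction), and the
# match / mismatch oppositions written target-probe. Decimal commas in the
# source normalized to points; everything else verbatim.
locus	str_distance_kb	set_name	mean_gc_pct	hit_distances	success_pct	best_tested_length	ddg_m_mm	sim_best_length	concordance	match_pair	mismatch_pair
P30	18	P30FG	36	no	76	21*	-1.15	21, 22	r	C-G	T-G
P30	18	P30FG-1	35	no	82	21	-1.80	21	r	C-G	T-G
P30	18	P30FA	33	no	83	20*	-0.40	21	r	T-A	C-A
P30	18	P30FA-1	30	no	95	22	-1.01	22	r	T-A	C-A
P30	18	P30RC	27	no	92	24*	-0.49	24	r	G-C	A-C
P30	18	P30RC-1	30	2, 24	70	23	-2.18	23, 27	r	G-C	A-C
P38	17	P38FA	77	no	89	21	-0.60	11	w	T-A	A-G
P38	17	P38FA-1	71	no	86	20	-1.04	12	w	T-A	A-G
P38	17	P38FC	83	2, 9, 10, 13+	72	15	-1.19	10	w	G-C	T-C
P38	17	P38FC-1	79	7, 10+	49	n.s.	-1.83	12	w	G-C	T-C
P224	13	P224FC	40	no	90	19*	-0.37	18	r	G-C	A-C
P224	13	P224FT	34	no	86	19*, 20*	-0.70	19	r	A-T	G-T
P224	13	P224RG	60	no	93	17	-1.31	14	r	C-G	T-G
P224	13	P224RA	53	no	86	17	-0.48	15, 16	r	T-A	C-A
P240	14	P240FC	37	no	82	22*	-0.48	22	r	G-C	A-C
P240	14	P240FC-1	40	no	83	20*	-2.43	20, 21	r	G-C	A-C
P240	14	P240FT	32	no	84	22	-0.60	22	r	A-T	T-C
P240	14	P240FT-1	35	no	94	20	-1.52	20, 21	r	A-T	T-C
P240	14	P240RG	42	no	79	18*	-1.14	19	r	C-G	T-G
P240	14	P240RG-1	40	no	73	20	-1.21	20	r	C-G	T-G
P240	14	P240RA	39	no	88	18	-0.87	18, 20	r	T-A	C-A
P244	35	P244FG	66	49	73	13*	-0.95	15	r	C-G	T-G
P244	35	P244FG-1	65	no	78	15	-2.11	14	r	C-G	T-G
P244	35	P244FA	57	116+	54	n.s.	0.05	no	r	T-A	C-A
P244	35	P244FA-1	59	0.6+	76	15	-1.04	15	r	T-A	C-A
P244	35	P244RC	68	20, 29+	68	14*	-0.66	13	r	G-C	A-C
P244	35	P244RC-1	71	20+	71	14	-2.16	14	r	G-C	A-C
P244	35	P244RT	60	2, 9, 13+	62	13	-0.69	13	r	A-T	G-T
P244	35	P244RT-1	64	9, 13+	66	14	-1.01	14	r	A-T	G-T
Tat	15	TatFT	33	no	84	20	-0.57	20	r	T-A	G-T
Tat	15	TatFC	38	no	87	18	-0.52	20	r	G-C	A-C
Tat	15	TatFG	40	no	75	19	-1.39	20	r	C-G	T-G
Tat	15	TatFG-1	43	no	81	18	-2.77	19, 20	r	C-G	T-G
rs13304202	37	rs13304202FA	34	no	77	19	0.42	no	w	T-A	C-A
rs13304202	37	rs13304202FA-1	38	no	76	22	-1.55	20, 22	r	T-A	C-A
rs13304202	37	rs13304202RC	39	no	70	21	-1.17	22	r	G-C	A-C
rs13304202	37	rs13304202RC-1	43	no	81	21*	-3.00	21, 24	r	G-C	A-C
Seq.E2071	0.3	Seq.E2071RG	35	no	78	20	-1.19	19	r	C-G	T-G
Seq.E2071	0.3	Seq.E2071RA	30	no	91	20	-0.13	20	r	T-A	C-A
Seq.F4204	0.15	Seq.F4204FG	53	0.3 kb with matched 3' end	67	17	-0.71	18	r	C-G	G-G
Seq.F4204	0.15	Seq.F4204FC	53	0.3 kb but no matched 3' end	98	17	-0.83	14	r	C-G	C-C
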