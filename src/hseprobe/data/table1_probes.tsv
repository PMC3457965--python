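# Probe sets tested in haplotype-specific extraction: name, printed
# mismatch pair (probe base - mismatched target base, as published),
# full-length 5'->3' sequence, and the verbatim tested-length token
# (5'-truncation series; "17, 19-22" means lengths 17 and 19 through 22).
# "-1" names place the discriminating base at the penultimate position.
# Transcribed verbatim from the published probe table, including the
# P240FT row's printed mismatch "C-A" (inconsistent with its T
# discriminator; flagged, not corrected).
set_name	mismatch	sequence	tested_lengths
P30FG	G-T	CAGGTGATAGATAAGTTGATCG	17, 19-22
P30FG-1	G-T	GGTGATAGATAAGTTGATCGA	21
P30FA	A-C	CAGGTGATAGATAAGTTGATCA	17, 19, 22
P30FA-1	A-C	AGGTGATAGATAAGTTGATCAA	21, 22
P30RC	C-A	TCTATCCATCTATCATCTATTTATC	19, 21, 24, 25
P30RC-1	C-A	TCTATCCATCTATCATCTATTTATCG	23, 26
P38FA	A-G	GCTGGGAGGGTGGCTCCCGCA	10-13, 15, 16, 19-21
P38FA-1	A-G	GGGAGGGTGGCTCCCGCAT	12, 16, 19
P38FC	C-T	CTGGGAGGGTGGCTCCCGCC	10, 12, 13, 15, 18-20
P38FC-1	C-T	GGAGGGTGGCTCCCGCCT	12, 18
P224FC	C-A	TCAGAAATGAGTGTGACATCTTC	9-21, 23
P224FT	T-G	TCAGAAATGAGTGTGACATCTTT	18-21, 23
P224RG	G-T	GTGGTTTCAGTCAGCAGGGG	17, 20
P224RA	A-C	GTGGTTTCAGTCAGCAGGGA	17, 20
P240FC	C-A	TCTTTCAGATCAATAACGTCTC	17, 19-22
P240FC-1	C-A	TTTCAGATCAATAACGTCTCG	18-21
P240FT	C-A	TCTTTCAGATCAATAACGTCTT	22
P240FT-1	C-A	TTTCAGATCAATAACGTCTTG	20, 21
P240RG	G-T	GTAGGCTCAGATAAAGAACG	16-20
P240RG-1	G-T	TAGGCTCAGATAAAGAACGA	19, 20
P240RA	A-C	GGTAGGCTCAGATAAAGAACA	17-21
P244FA	A-C	CAGTGCAACAGGACCA	14, 16, 23
P244FA-1	A-C	AGTGCAACAGGACCAG	15, 16
P244FG	G-T	GCCCAGCAGTGCAACAGGACCG	11-16, 23
P244FG-1	G-T	GTGCAACAGGACCGG	13-15
P244RC	C-A	TATTGTCCTGCAGCTCCATCCCC	13-15, 23
P244RC-1	C-A	CAGCTCCATCCCCG	13, 14
P244RT	T-G	ATTGTCCTGCAGCTCCATCCCT	11, 13, 16, 22
P244RT-1	T-G	CAGCTCCATCCCTG	14
TatFT	T-G	GTGTAGACTTGTGAATTCAT	20
TatFC	C-A	GTGTAGACTTGTGAATTCAC	18, 20
rs13304202FA	A-C	TAAGGAACATTACTCAAGAGA	18-21
rs13304202FA-1	A-C	TAAGGAACATTACTCAAGAGAC	20, 22
rs13304202FG	G-T	TAAGGAACATTACTCAAGAGG	21
rs13304202FG-1	G-T	GGAACATTACTCAAGAGGC	19
rs13304202RC	A-C	AGTTTTATTTATGGAGGAAGC	18, 19, 21
rs13304202RC-1	A-C	TTAGTTTTATTTATGGAGGAAGCC	19-21, 24
Seq.E2071RG	G-T	AGGCTGTGCTATTGATGAAAATG	20, 23
Seq.E2071RA	A-C	AGGCTGTGCTATTGATGAAAATA	20, 23
Seq.F4204FG	G-G	GGTCTTCCTCTGTTCCTCAG	17, 20
Seq.F4204FC	C-C	GGTCTTCCTCTGTTCCTCAC	17, 20
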