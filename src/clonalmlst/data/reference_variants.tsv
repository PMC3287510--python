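complex	locus	founder_allele	variant_allele	n_diffs	seen_elsewhere	member_sts
I	trmD	1	3	1	1	9
I	trmD	1	10	15	0	5
I	groEL	8	4	4	0	2,1
I	ftsZ	2	1	1	0	1
I	trmD	1	6	7	0	11,6
I	wsp	1	5	18	0	6
II	trmD	1	14	9	0	29
II	trmD	1	6	7	0	28
II	trmD	1	2	1	1	27
III	wsp	5	3	8	0	15
III	groEL	8	4	4	0	14
III	trmD	1	5	2	0	13
IV	trmD	8	17	9	0	36
IV	trmD	8	15	8	0	10,12
IV	wsp	12	4	16	0	12
IV	groEL	12	11	2	1	25
V	trmD	9	11	1	1	34
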