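complex	st	wsp	ftsZ	groEL	trmD	freq	is_founder
I	4	1	2	8	1	2	1
I	9	1	2	8	3	1	0
I	5	1	2	8	10	1	0
I	2	1	2	4	1	12	0
I	1	1	1	4	1	1	0
I	11	1	2	8	6	1	0
I	6	5	2	8	6	1	0
II	30	12	10	8	1	1	1
II	29	12	10	8	14	1	0
II	28	12	10	8	6	1	0
II	27	12	10	8	2	1	0
III	16	5	3	8	1	2	1
III	15	3	3	8	1	1	0
III	14	5	3	4	1	1	0
III	13	5	3	8	5	1	0
IV	24	12	10	12	8	3	1
IV	36	12	10	12	17	1	0
IV	10	12	10	12	15	1	0
IV	12	4	10	12	15	1	0
IV	25	12	10	11	8	1	0
V	33	6	14	3	9	8	1
V	34	6	14	3	11	1	0
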