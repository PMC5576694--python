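category	egfr_activating	t790m	first_biopsy	pre_afatinib	post_afatinib	wes
Exon 18	1	0	1	0	1	0
Exon 19	1	0	24	4	5	2
Exon 19 + T790M	1	1	0	18	6	1
WT (WES only)	0	0	0	0	0	1
Exon 21	1	0	7	2	2	0
Exon 21 + T790M	1	1	0	4	2	2
Exon 18 + 20	1	0	1	1	0	0
WT	0	0	4	4	2	0
Exon 18 + 21 + T790M	1	1	0	0	0	1
Mutation analysis not possible	0	0	1	0	0	0
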