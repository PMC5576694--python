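gene	patient	chrom	pos	ref	alt	aa_change	cadd
HLA-DRB1	#2	6	32552130	C	A	R42S	0.145
HLA-DRB1	#2	6	32552131	C	G	R42T	0.005
HLA-DRB1	#6	6	32552134	T	G	K41T	10.93
HLA-DRB1	#3	6	32552130	C	A	R42S	0.145
HLA-DRB1	#3	6	32552132	T	A	R42W	10.52
HLA-DRB1	#4	6	32548544	T	G	I248L	16.04
HLA-DRB1	#7	6	32552130	C	A	R42S	0.145
HLA-DRB1	#7	6	32552131	C	G	R42T	0.005
HLA-DRB1	#7	6	32552137	G	C	P40R	0
HLA-DRB1	#7	6	32552138	G	C	P40A	0.005
HLA-DRB1	#7	6	32552143	C	T	W38*	13.84
HLA-DRB1	#7	6	32552144	A	C	W38G	3.518
AQP7	#2	9	33385808	G	T	N194K	15.08
AQP7	#5	9	33385709	C	T	V96I	9.787
AQP7	#5	9	33385712	G	A	P95S	10.22
AQP7	#5	9	33385690	C	T	R234S	14.5
AQP7	#5	9	33385698	A	G	L231P	16.61
AQP7	#1	9	33385712	G	A	P95S	10.22
AQP7	#4	9	33395131	TG	T	Q30	NA
FAM198A	#2	3	43074734	C	A	P327T	9.704
FAM198A	#6	3	43074337	G	T	W194C	14.09
SEC31A	#5	4	83803067	C	T	R8H	27.8
SEC31A	#6	4	83784534	CT	C	E482	NA
CNTLN	#2	9	17366624	TGAA	T	E633	NA
CNTLN	#5	9	17236574	TG	T	A280	NA
CNTLN	#5	9	17236576	C	A	A280E	5.077
ESX1	#2	X	103497493	G	C	R175G	11.68
ESX1	#6	X	103498982	C	A	G120V	14.79
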