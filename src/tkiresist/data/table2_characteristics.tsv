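characteristic	category	t790m_positive	t790m_negative
Sex	Male	4	2
Sex	Female	18	5
ECOG Performance status	0	12	1
ECOG Performance status	1	9	6
ECOG Performance status	2	1	0
Ethnic origin	White	19	7
Ethnic origin	Asian	2	0
Ethnic origin	Afro-American	1	0
Smoking history	Never smoker	10	5
Smoking history	Ex-smoker	10	1
Smoking history	Current smoker	0	0
Smoking history	Unknown	2	1
Number of lines of previous chemotherapy	0	11	1
Number of lines of previous chemotherapy	1	3	4
Number of lines of previous chemotherapy	2	6	2
Number of lines of previous chemotherapy	>2	2	0
EGFR TKI before afatinib	erlotinib	18	1
EGFR TKI before afatinib	gefitinib	2	6
EGFR TKI before afatinib	both subsequently	4	1
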