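codon	sequence	hotspot_status	observed_gt	printed_p
157	CCCGCGTCCGC	Lung	27	1e-27
158	CGTCCGCGCCA	Lung	35	4e-39
245	TGGGCGGCATG	Many	9	4e-6
248	GAACCGGAGGC	Many	24	2e-23
273	GGTGCGTGTTT	Many	36	1e-40
282	AGACCGGCGCA	Many	1	0.362
170	ATGACGGAGGT	None	0	0.303
186	ATAGCGATTGT	None	0	0.303
213	TTTTCGACATA	Breast	2	0.216
267	GGGACGGAACA	None	0	0.303
290	TCTCCGCAAGA	None	2	0.216
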