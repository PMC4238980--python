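cohort	variable	comparison	gene	odds_ratio	ci_low	ci_high	p
TCGA_Provisional	disease_free_status	Disease free vs. recurred	CXCL14	1.62	1.10	2.38	0.014
TCGA_Provisional	disease_free_status	Disease free vs. recurred	RNASEH2A	2.17	1.04	4.52	0.038
TCGA_Provisional	pathological_stage	T2 vs. T3+T4	LPCAT2	1.44	1.02	2.03	0.038
GSE21032	pathological_stage	T2 vs. T3+T4	CXCL14	1.75	1.19	2.59	0.005
GSE21032	gleason_score	<7 vs. >=7	CCL19	0.46	0.24	0.88	0.019
GSE21032	gleason_score	<7 vs. >=7	HIST1H1A	0.45	0.24	0.86	0.017
GSE21032	gleason_score	<7 vs. >=7	ITGAX	3.78	1.88	7.56	0.0002
GSE21032	gleason_score	<7 vs. >=7	ZNF322	2.26	1.27	4.02	0.006
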