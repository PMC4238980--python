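trait	chrom	lod	genome_p	peak_cM	ci_start_bp	ci_end_bp
distant_metastasis_free_survival	1	3.93	0.042	35.0	40760231	95290730
distant_metastasis_free_survival	11	3.97	0.039	30.9	41325431	69191538
nodal_metastasis_burden	13	4.69	0.011	22.1	4829663	46774063
liver_surface_metastasis_count	11	4.01	0.037	8.6	11062569	35356130
prostate_tumor_burden	13	4.86	0.007	18.7	4758113	60501553
seminal_vesicle_tumor_burden	2	5.01	0.005	84.4	146404042	165979416
seminal_vesicle_tumor_burden	4	5.24	0.003	7.6	5191558	53264210
seminal_vesicle_tumor_burden	8	4.22	0.022	52.8	83633294	111798566
seminal_vesicle_tumor_burden	17	5.20	0.004	11.1	3499649	36093828
age_of_death	7	4.35	0.0009	76.4	122268816	144131415
age_of_death	8	4.65	0.0009	50.8	87425863	111798566
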