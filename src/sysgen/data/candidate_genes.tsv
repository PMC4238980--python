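trait	chrom	snp_id	snp_bp	transcript	beta	t_stat	eqtl_p	eqtl_fdr	corr_r	corr_p	corr_fdr	founder_direction	mouse_gene	human_ortholog
age_of_death	7	rs13479522	128129547	NM_021334	-0.30	-3.11	0.002	0.045	0.31	0.0004	0.004	C57BL/6J	Itgax	ITGAX
age_of_death	8	rs13479871	84956610	ENSMUST00000109736	0.08	3.57	0.001	0.014	-0.22	0.012	0.046	NOD/ShiLtJ	Rnaseh2a	RNASEH2A
dmfs	11	rs3711357	61505144	ENSMUST00000102657	0.16	6.64	9.15E-10	1.07E-07	NA	0.004	0.021	NOD/ShiLtJ	B9d1	B9D1
primary_tumor_burden	13	rs8267104	23763668	NM_030609	-0.42	-5.04	1.63E-06	9.88E-05	0.25	0.004	0.022	C57BL/6J	Hist1h1a	HIST1H1A
primary_tumor_burden	13	rs8267104	23751088	NM_175660	-0.92	-10.75	2.50E-19	2.06E-16	0.24	0.008	0.034	C57BL/6J	Hist1h2ab	HIST1H2AB
primary_tumor_burden	13	rs8267104	23760692	BC119241	-0.14	-3.50	0.001	0.017	0.32	0.0003	0.003	C57BL/6J	Hist1h4a	HIST1H4A
primary_tumor_burden	13	rs8267104	23353103	NM_001111107	-0.20	-5.84	4.42E-08	3.67E-06	0.29	0.001	0.006	NOD/ShiLtJ	Zfp322a	ZNF322
primary_tumor_burden	13	rs8267104	23535418	ENSMUST00000080859	-0.20	-4.06	8.52E-05	0.003	0.22	0.012	0.046	C57BL/6J	Hist1h3g	HIST1H3E
primary_tumor_burden	13	rs8267104	23744973	ENSMUST00000091752	-0.29	-6.45	2.39E-09	2.57E-07	0.25	0.004	0.020	C57BL/6J	Hist1h3c	HIST1H3C
primary_tumor_burden	13	rs8267104	23527011	AK006302	-0.37	-6.87	2.88E-10	3.81E-08	0.28	0.002	0.011	C57BL/6J	Hist1h4h	HIST1H4H
primary_tumor_burden	13	rs3720782	55623005	NM_007596	-0.10	-4.02	9.81E-05	0.004	0.24	0.006	0.029	C57BL/6J	Caml	CAMLG
primary_tumor_burden	13	rs3720782	56288643	NM_019568	0.31	3.12	0.002	0.045	-0.36	3.73E-05	0.001	NOD/ShiLtJ	Cxcl14	CXCL14
primary_tumor_burden	13	rs3679784	21421275	NM_001162920	0.21	3.58	4.81E-04	0.013	0.23	0.011	0.044	NOD/ShiLtJ	Pgbd1	PGBD1
primary_tumor_burden	13	rs6275055	24943152	NM_008156	-0.51	-6.56	1.37E-09	1.52E-07	-0.32	0.0004	0.002	C57BL/6J	Gpld1	GPLD1
seminal_vesicle_tumor_burden	2	rs6209325	148681023	ENSMUST00000028928	0.09	3.40	0.001	0.022	-0.25	0.005	0.024	C57BL/6J	Gzf1	GZF1
seminal_vesicle_tumor_burden	2	gnf02.149.271	151494182	NM_198326	-0.10	-4.93	2.58E-06	1.49E-04	-0.28	0.002	0.010	NOD/ShiLtJ	Nsfl1c	NSFL1C
seminal_vesicle_tumor_burden	2	rs6247960	153345845	ENSMUST00000109790	-0.08	-3.22	0.002	0.034	-0.37	1.55E-05	0.0004	C57BL/6J	Asxl1	ASXL1
seminal_vesicle_tumor_burden	2	rs6376291	153345845	ENSMUST00000109790	0.08	3.30	0.001	0.028	-0.37	1.55E-05	0.0004	NOD/ShiLtJ	Asxl1	ASXL1
seminal_vesicle_tumor_burden	2	rs13476860	155817730	NM_010808	0.16	6.17	9.02E-09	8.72E-07	-0.33	0.0002	0.002	NOD/ShiLtJ	Mmp24	MMP24
seminal_vesicle_tumor_burden	4	rs13477643	34550615	NM_001007589	0.13	4.44	1.94E-05	0.001	-0.33	0.0002	0.002	NOD/ShiLtJ	Akirin2	AKIRIN2
seminal_vesicle_tumor_burden	4	rs13477643	34566781	NM_015824	0.15	4.78	4.86E-06	2.65E-04	-0.47	2.38E-08	4.67E-06	NOD/ShiLtJ	Orc3	ORC3
seminal_vesicle_tumor_burden	4	rs3698283	42629332	NM_011888	0.36	9.51	2.31E-16	9.27E-14	-0.41	1.71E-06	6.85E-05	NOD/ShiLtJ	Ccl19	CCL19
seminal_vesicle_tumor_burden	4	rs3698283	42916660	ENSMUST00000107976	-0.23	-3.58	4.81E-04	0.014	-0.29	0.001	0.008	C57BL/6J	N28178	KIAA1045
seminal_vesicle_tumor_burden	4	rs3698283	42979963	NM_009503	-0.14	-8.03	6.98E-13	1.55E-10	-0.24	0.006	0.029	C57BL/6J	Vcp	VCP
seminal_vesicle_tumor_burden	4	rs3698283	42714926	NR_033123	-0.51	-5.55	1.70E-07	1.23E-05	-0.30	0.001	0.006	NOD/ShiLtJ	4933409K07Rik	None
seminal_vesicle_tumor_burden	4	rs3698283	43654227	NM_026871	-0.15	-4.49	1.59E-05	7.52E-04	0.32	0.0003	0.003	C57BL/6J	Hint2	HINT2
seminal_vesicle_tumor_burden	4	rs3698283	42736593	ENSMUST00000144765	-0.37	-4.85	3.67E-06	2.05E-04	0.30	0.001	0.005	C57BL/6J	Gm12395	None
seminal_vesicle_tumor_burden	4	rs3698283	42206998	ENSMUST00000169242	0.37	4.14	6.32E-05	0.002	-0.42	7.61E-07	3.69E-05	NOD/ShiLtJ	Gm17167	None
seminal_vesicle_tumor_burden	4	rs3698283	42244362	BC059060	0.46	4.54	1.31E-05	0.001	-0.42	1.08E-06	5.03E-05	NOD/ShiLtJ	Gm3893	None
seminal_vesicle_tumor_burden	4	rs13477643	34949074	NM_178061	-0.52	-5.95	2.58E-08	2.25E-06	0.28	0.001	0.009	C57BL/6J	Mob3b	MOB3B
seminal_vesicle_tumor_burden	4	rs13477643	34768664	BC027508	-0.19	-7.35	2.48E-11	4.43E-09	0.31	0.0004	0.004	C57BL/6J	Smim8	SMIM8
seminal_vesicle_tumor_burden	8	rs13479922	92855350	NM_173014	-0.35	-3.83	1.98E-04	0.007	0.25	0.006	0.026	C57BL/6J	Lpcat2	LPCAT2
seminal_vesicle_tumor_burden	17	rs3719497	24528251	NR_045289	0.19	4.35	2.79E-05	0.001	-0.30	0.001	0.006	NOD/ShiLtJ	Rab26os	None
seminal_vesicle_tumor_burden	17	rs3719497	25240170	NM_026676	-0.10	-3.15	0.002	0.041	-0.23	0.011	0.043	C57BL/6J	Tsr3	TSR3
liver_surface_metastasis_count	11	rs3023251	21344588	NR_035454	-0.48	-8.43	8.55E-14	2.23E-11	-0.25	0.005	0.023	C57BL/6J	Mir1933	None
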