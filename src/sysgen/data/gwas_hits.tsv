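cytoband	gene	distance_bp	snp_id	variable	odds_ratio	ci_low	ci_high	maf_aggressive	maf_nonaggressive	t_stat	p	perm_p
5q31.1	CXCL14	97285	rs801564	pros_stage_n	1.05	1.01	1.09	0.001	0.282	2.587	0.010	0.011
5q31.1	CXCL14	47017	rs10515473	pros_gleason_prost	0.72	0.59	0.88	0.163	0.122	-3.148	0.002	0.001
6p22.1	HIST1H3E	6834	rs933199	pros_gleason	0.75	0.62	0.92	0.032	0.025	-2.759	0.006	0.006
6p22.1	HIST1H3E	17168	rs198806	pros_gleason_prost	0.77	0.63	0.93	0.218	0.172	-2.643	0.008	0.009
6p22.1	PGBD1	31884	rs1233708	pros_stage	1.08	1.02	1.13	0.042	0.213	2.921	0.004	0.004
6p22.2	HIST1H1A	13705	rs6910741	pros_stage_n	0.94	0.90	0.98	0.002	0.144	-2.620	0.009	0.009
6p22.3	GPLD1	0	rs793663	pros_gleason_prost	1.32	1.09	1.60	0.186	0.195	2.854	0.004	0.004
6p22.3	GPLD1	37981	rs3789224	pros_stage_m	1.08	1.02	1.13	0.000406	0.127	2.627	0.009	0.010
6q15	AKIRIN2	0	rs7755167	pros_gleason	0.86	0.78	0.95	0.246	0.221	-3.107	0.002	0.002
6q15	ORC3	40224	rs9450716	pros_gleason	1.16	1.05	1.28	0.161	0.189	3.042	0.002	0.002
9p13.3	CCL19	80925	rs3802427	pros_stage_m	1.09	1.04	1.15	0.000406	0.162	3.557	0.000389	0.0003
9p13.3	KIAA1045	78052	rs10123308	pros_gleason_prost	1.30	1.08	1.57	0.212	0.216	2.773	0.006	0.005
9p21.2	MOB3B	3431	rs3849942	pros_stage_t	2.15	1.41	3.28	0.161	0.075	3.564	0.00038	0.0005
9p21.2	MOB3B	0	rs3739530	pros_gleason	0.80	0.70	0.93	0.075	0.056	-2.996	0.003	0.002
9p21.2	MOB3B	74176	rs1853186	pros_stage	0.94	0.90	0.98	0.079	0.272	-2.730	0.006	0.006
9p21.2	MOB3B	0	rs10121765	pros_gleason_prost	0.77	0.64	0.93	0.260	0.209	-2.776	0.006	0.005
16p11.2	ITGAX	9009	rs8045738	pros_gleason_prost	1.33	1.08	1.62	0.141	0.148	2.753	0.006	0.007
16q12.2	LPCAT2	19704	rs3764263	pros_stage_t	1.61	1.12	2.31	0.324	0.134	2.591	0.010	0.009
16q12.2	LPCAT2	0	rs289707	pros_gleason_biop	1.22	1.07	1.38	0.075	0.126	3.059	0.002	0.002
16q12.2	LPCAT2	72508	rs2289119	pros_stage_n	1.06	1.01	1.10	0.001	0.187	2.591	0.010	0.009
16q12.2	LPCAT2	0	rs17369578	pros_gleason	1.41	1.13	1.77	0.020	0.026	2.976	0.003	0.003
20p11.21	GZF1	836	rs6076072	pros_stage_t	2.17	1.21	3.92	0.068	0.035	2.589	0.010	0.008
20p13	NSFL1C	4463	rs6042568	pros_gleason	0.75	0.62	0.90	0.037	0.029	-3.007	0.003	0.003
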