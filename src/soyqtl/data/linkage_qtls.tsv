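trait	env	name	chrom	additive	lod	pve	start_bp	end_bp	size_mb_published
PH	2013	qPH-m-1	Gm07	-7.74	4.61	4.33	3900022	3934584	0.03
PH	2013	qPH-o-1	Gm10	-8.45	6.61	6.36	2643396	2728613	0.09
PH	2013	qPH-o-2	Gm10	9.85	10.94	11.06	45348039	45606087	0.26
PH	2013	qPH-j-1	Gm16	-7.65	15.89	17.04	32755660	32778805	0.02
PH	2013	qPH-g-1	Gm18	6.22	5.91	5.63	57614442	57682794	0.07
PH	2013	qPH-i-1	Gm20	4.61	3.34	3.09	33541216	33591497	0.05
PH	2014	qPH-k-1	Gm09	11.42	9.66	21.70	38984325	39808126	0.82
PH	2014	qPH-o-3	Gm10	-6.76	3.31	6.80	3044123	3089804	0.05
PH	2014	qPH-d2-1	Gm17	6.68	3.24	6.65	38033581	38140597	0.11
PH	2015	qPH-c1-1	Gm04	6.01	5.16	10.22	51165545	51205951	0.04
PH	2015	qPH-j-2	Gm16	-6.63	4.26	9.14	31527228	31708328	0.18
PH	2016	qPH-d1a-1	Gm01	-5.68	6.47	6.88	4956352	5012034	0.06
PH	2016	qPH-d1a-2	Gm01	4.14	4.06	4.26	27204683	27663584	0.46
PH	2016	qPH-c1-2	Gm04	7.05	12.74	13.97	51206176	51248063	0.04
PH	2016	qPH-m-2	Gm07	-6.92	6.90	7.36	36657129	36690007	0.03
PH	2016	qPH-o-4	Gm10	-5.82	3.08	3.13	2733103	2932573	0.20
PH	2016	qPH-b1-1	Gm11	9.81	3.80	3.89	24409526	25442397	1.03
PH	2016	qPH-e-1	Gm15	-5.14	4.50	4.72	14578705	14885298	0.31
PH	2016	qPH-j-3	Gm16	-5.34	6.51	6.98	31822329	31845684	0.02
PH	2016	qPH-l-1	Gm19	-5.10	6.36	6.78	46391451	46417246	0.03
PH	BLUE	qPH-c2-1	Gm06	-7.96	11.71	9.74	3612257	3655776	0.04
PH	BLUE	qPH-m-3	Gm07	-5.62	5.51	4.26	4023721	4389344	0.37
PH	BLUE	qPH-j-4	Gm16	-3.34	6.26	4.89	31484839	31506867	0.03
PH	BLUE	qPH-g-2	Gm18	6.27	7.63	6.05	54901888	54960317	0.06
NNMS	2014	qMS-d1a-1	Gm01	2.09	2.87	6.97	50129391	50289706	0.16
NNMS	2014	qMS-a2-1	Gm08	-1.25	2.68	6.50	22007790	22273422	0.27
NNMS	2014	qMS-j-1	Gm16	-1.20	3.22	8.18	30783034	30820945	0.04
NNMS	2016	qMS-c2-1	Gm06	1.92	4.40	5.90	4184901	4275666	0.09
NNMS	2016	qMS-c2-2	Gm06	-3.61	10.37	15.07	10205331	10819289	0.61
NNMS	2016	qMS-h-1	Gm12	1.62	6.32	8.91	1733331	1854712	0.12
NNMS	2016	qMS-j-2	Gm16	-1.34	3.85	5.19	3261870	3556117	0.29
NNMS	2016	qMS-l-1	Gm19	1.76	3.72	5.00	3626636	3814283	0.19
NNMS	BLUE	qMS-k-1	Gm09	2.00	12.19	20.12	39484325	39808126	0.82
NNMS	BLUE	qMS-h-2	Gm12	0.95	5.42	8.47	2635139	2693348	0.06
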