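family	n_members	reads_ck	reads_tr	norm_ck	norm_tr	log2fc
miR171	29	343	44	26.76	9.22	-1.54
miR156	27	1355	1598	105.67	337.44	1.68
miR166	24	159766	7058	12462.71	1490.18	-3.06
miR159	21	113946	3148	8888.52	664.54	-3.74
miR169	20	324	74	25.27	15.62	-0.69
miR167	19	6488	653	506.08	137.93	-1.88
miR396	19	12312	1553	960.41	327.80	-1.55
miR812	13	126	36	9.83	7.60	-0.37
miR397	12	62874	1547	4904.56	326.54	-3.91
miR172	10	6	15	0.47	3.17	2.76
miR164	10	71	61	5.56	12.81	1.20
miR398	10	3104	1433	242.11	302.61	0.32
miR395	10	89	1	6.97	0.14	-5.64
miR160	9	312	366	24.31	77.20	1.67
miR319	9	1018	80	79.41	16.96	-2.23
miR408	8	36263	3877	2828.76	818.59	-1.79
miR444	7	463	155	36.12	32.79	-0.14
miR1861	7	106	38	8.24	8.09	-0.03
miR162	6	5316	859	414.65	181.28	-1.19
miR393	6	7	1	0.57	0.14	-2.02
miR390	5	76	7	5.95	1.41	-2.08
miR1846	5	12	6	0.91	1.34	0.56
miR1863	5	23	12	1.77	2.53	0.52
miR535	4	46	12	3.56	2.53	-0.49
miR1432	4	364	202	28.37	42.65	0.59
miR2118	3	1	2	0.08	0.35	ND
miR810	3	33	28	2.60	5.98	1.20
miR482	3	39	0	3.04	0.01	-8.25
miR168	3	358	138	27.93	29.21	0.06
miR399	3	3	0	0.23	0.01	ND
miR2863	3	31	31	2.42	6.54	1.44
miR1862	3	4565	469	356.12	99.09	-1.85
miR1120	3	4	2	0.31	0.42	ND
miR529	3	4	0	0.31	0.01	ND
miR1882	2	3831	9339	298.84	1971.68	2.72
miR3522	2	2	0	0.16	0.01	ND
miR1878	2	8	7	0.62	1.48	1.24
miR1428	2	3	0	0.23	0.01	ND
miR2871	2	17	8	1.33	1.69	0.35
miR1437	2	6	1	0.47	0.14	-1.73
miR528	2	2047	699	159.68	147.57	-0.11
miR3630	2	101	98	7.88	20.69	1.39
miR1440	2	2	0	0.16	0.01	ND
miR2873	2	5	2	0.39	0.42	0.11
miR5143	1	14	3	1.09	0.56	-0.96
miR5160	1	0	1	0.03	0.21	ND
miR1122	1	1	1	0.05	0.14	ND
miR439	1	2	2	0.13	0.35	ND
miR2275	1	0	1	0.01	0.21	ND
miR2121	1	2	1	0.16	0.14	ND
miR814	1	4	7	0.29	1.55	2.44
miR5539	1	1	0	0.08	0.01	ND
miR820	1	1066	197	83.15	41.59	-1.00
miR827	1	2	0	0.18	0.07	ND
miR1511	1	10	0	0.78	0.01	-6.29
miR5157	1	1	0	0.08	0.01	ND
miR1883	1	185	2	14.46	0.49	-4.88
miR1319	1	6	1	0.44	0.21	-1.07
miR5534	1	1	0	0.08	0.01	ND
miR8155	1	10	0	0.78	0.01	-6.29
miR5148	1	4	1	0.31	0.21	ND
miR5079	1	30	71	2.34	15.06	2.69
miR394	1	35	3	2.73	0.56	-2.28
miR9863	1	1	0	0.08	0.01	ND
miR530	1	1	1	0.08	0.14	ND
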