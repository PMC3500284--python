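pdb_id	rmsd100_native_sse	rmsd100_native_complete	rmsd100_predicted_sse	rmsd100_predicted_complete	rmsd100_comparator	cr_native_sse	cr_native_complete	cr_predicted_sse	cr_predicted_complete	cr_comparator
1BGCA	2.94	4.25	5.41	6.29	7.06	61.11	59.26	45.37	49.07	42.59
1EYHA	6.06	6.92	5.87	7.20	4.30	28.69	31.15	41.80	37.70	40.77
1FQIA	7.17	7.60	6.20	8.06	5.37	38.46	36.92	40.00	44.62	32.58
1GAKA	4.90	7.06	6.38	7.69	4.60	42.59	42.59	29.63	32.41	66.67
1GYUA	4.41	6.39	4.11	6.39	5.96	58.68	58.68	61.16	61.16	51.24
1IAPA	6.46	7.55	7.38	8.23	5.65	27.12	27.12	22.03	22.03	19.11
1ICXA	6.51	6.80	6.07	6.46	5.59	45.74	46.28	51.06	48.40	37.44
1J27A	3.20	3.62	3.15	3.72	4.49	71.20	70.40	68.80	70.40	54.07
1JL1A	6.04	8.01	6.75	8.19	8.26	39.05	43.33	31.43	34.76	26.52
1LKIA	2.90	5.40	7.07	9.10	7.18	59.29	59.29	23.01	29.20	36.70
1LMIA	5.82	8.60	6.72	9.97	9.49	49.65	48.94	29.08	31.21	26.95
1OXJA	6.42	7.67	7.21	7.79	6.75	44.68	45.74	30.85	30.85	45.45
1OZ9A	5.78	6.88	5.22	5.93	5.39	38.36	43.40	40.25	40.88	37.50
1PBVA	8.02	9.02	8.75	9.14	6.47	28.30	28.30	30.19	31.13	40.00
1PKOA	6.03	7.81	7.58	8.15	8.43	43.07	40.88	38.69	39.42	27.74
1Q5ZA	5.64	8.03	7.28	8.56	8.93	40.00	40.00	41.54	43.08	21.28
1RJ1A	4.66	5.52	4.86	5.33	3.33	48.43	48.43	55.97	57.23	45.56
1T3YA	5.71	5.92	5.86	6.56	6.27	49.61	51.94	42.64	44.96	34.06
1TP6A	4.91	5.65	5.74	6.83	5.25	49.65	53.15	46.15	47.55	44.59
1TQGA	1.91	2.19	1.92	2.44	1.41	76.40	76.40	76.40	76.40	93.55
1TZVA	4.55	6.01	4.89	5.58	3.20	46.28	46.28	39.67	39.67	45.45
1UAIA	6.13	7.95	7.24	9.05	9.62	38.58	37.01	29.53	31.50	16.54
1ULRA	3.17	4.82	3.61	4.73	4.18	62.14	63.11	66.02	70.87	53.98
1VINA	7.42	8.53	7.62	8.68	8.48	25.46	25.46	20.83	21.76	21.98
1X91A	2.40	3.30	4.08	4.49	2.49	77.64	77.64	48.45	49.07	68.02
1XAKA	8.17	9.53	5.28	7.77	8.67	53.03	53.03	31.82	48.48	34.85
1XKRA	6.14	7.29	8.04	8.47	8.79	28.47	30.29	27.37	32.48	24.51
1XQOA	8.05	8.71	7.50	8.20	9.16	18.82	18.28	18.82	19.35	14.73
1Z3XA	7.74	9.19	7.58	9.59	8.44	24.27	24.27	22.33	22.33	30.37
2AP3A	2.78	3.16	3.67	6.06	4.17	52.52	51.08	43.17	42.45	52.26
2BK8A	5.09	6.89	4.81	7.13	4.27	56.41	57.69	55.13	55.13	80.77
2CWRA	5.99	6.05	5.66	7.63	7.46	45.80	45.04	44.27	48.85	26.72
2EJXA	6.28	6.64	7.48	7.89	5.17	41.43	42.14	29.29	35.00	38.82
2F1SA	6.68	7.93	7.61	8.26	7.34	27.27	28.28	25.25	26.26	27.27
2FC3A	4.90	7.39	5.63	6.78	5.75	34.62	40.00	36.92	46.92	25.36
2FM9A	6.22	7.05	6.26	6.95	6.37	24.05	24.05	21.52	22.78	25.14
2FRGP	4.67	5.69	5.38	6.41	6.53	57.02	56.14	53.51	53.51	35.96
2GKGA	3.43	4.31	3.89	4.40	3.45	52.10	52.94	47.06	48.74	58.20
2HUJA	2.12	2.98	2.57	3.37	3.65	71.31	71.31	66.39	67.21	47.29
2IU1A	6.70	7.99	6.84	8.04	7.16	25.16	25.79	20.13	23.27	27.06
2JLIA	6.18	7.11	6.93	8.14	6.46	46.59	46.59	37.50	42.05	36.89
2LISA	4.77	6.03	5.47	7.22	5.71	43.33	43.33	41.11	45.56	59.79
2OF3A	8.92	9.26	8.25	9.30	8.30	20.24	20.65	19.43	20.65	26.58
2OSAA	6.55	7.78	7.21	8.82	8.05	27.14	27.14	28.57	32.86	24.86
2QZQA	5.48	8.73	6.10	8.40	9.89	63.24	61.03	47.06	52.94	34.81
2R0SA	6.95	9.53	7.80	10.29	10.27	24.49	24.49	23.13	23.13	21.30
2RB8A	3.27	5.07	2.91	5.09	4.91	62.11	61.05	68.42	70.53	60.00
2RCIA	5.32	6.99	9.17	10.20	10.29	47.50	48.75	22.08	24.58	16.06
2V75A	3.26	3.66	3.11	3.55	2.29	67.12	65.75	60.27	60.27	85.71
2VQ4A	4.18	6.65	5.28	7.20	9.18	57.94	57.01	59.81	59.81	36.45
2WJ5A	5.80	8.48	6.41	8.63	7.86	67.80	66.10	71.19	71.19	77.97
2WWEA	4.92	6.43	5.30	6.22	5.97	45.95	48.65	48.65	48.65	41.38
2YV8A	5.71	7.85	5.54	7.48	8.53	47.62	47.02	43.45	41.07	26.19
2YXFA	5.84	7.28	6.13	6.65	4.38	51.46	51.46	48.54	51.46	53.40
2YYOA	6.68	8.55	6.72	7.94	9.13	37.91	39.22	40.52	41.18	23.53
2ZCOA	7.75	8.42	7.63	8.33	8.20	18.28	19.03	18.28	19.03	17.18
3B5OA	6.46	7.28	8.62	8.96	9.10	23.11	23.11	9.78	15.11	11.43
3CTGA	5.52	6.89	5.61	6.93	4.07	52.11	53.52	45.07	50.70	48.72
3CX2A	4.96	7.88	7.27	7.04	8.20	54.37	54.37	49.51	54.37	47.57
3FH2A	6.37	7.34	6.35	7.55	4.73	33.33	33.97	27.56	28.21	41.85
3FHFA	8.60	9.17	7.81	8.88	7.54	19.42	21.36	16.50	18.45	27.07
3FRRA	6.50	7.50	4.53	5.87	5.46	30.82	30.82	33.33	34.59	45.25
3HVWA	6.10	8.02	6.48	6.49	6.69	39.61	40.26	30.52	37.66	25.95
3IV4A	3.34	4.68	4.54	5.80	3.98	60.61	61.62	52.53	49.49	40.95
3NE3B	5.01	5.65	6.41	7.01	5.60	45.45	48.25	48.25	51.05	34.10
3OIZA	4.48	5.00	5.76	6.21	4.20	50.00	50.96	30.77	41.35	56.76
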