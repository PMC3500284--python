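pdb_id	full_naa	full_nsse	full_nhelix	full_nstrand	full_co	full_rco	filt_naa	filt_nsse	filt_nhelix	filt_nstrand	filt_co	filt_rco
1BGCA	174	7	7	0	67.75	0.39	108	5	5	0	81.94	0.47
1EYHA	144	8	8	0	33.59	0.23	107	8	8	0	36.48	0.25
1FQIA	147	9	9	0	44.35	0.30	90	9	9	0	46.87	0.32
1GAKA	141	7	7	0	57.17	0.41	96	6	6	0	51.38	0.36
1GYUA	140	10	2	8	34.86	0.25	63	8	0	8	32.51	0.23
1IAPA	211	11	11	0	60.11	0.28	123	9	9	0	77.40	0.37
1ICXA	155	13	6	7	47.25	0.30	103	10	3	7	46.52	0.30
1J27A	102	6	2	4	44.41	0.44	76	6	2	4	46.89	0.46
1JL1A	155	10	5	5	52.69	0.34	97	10	5	5	50.41	0.33
1LKIA	180	8	6	2	73.33	0.41	113	5	5	0	76.37	0.42
1LMIA	131	10	1	9	40.95	0.31	63	9	0	9	41.77	0.32
1OXJA	173	11	11	0	35.54	0.21	108	8	8	0	30.49	0.18
1OZ9A	150	10	5	5	34.00	0.23	101	9	5	4	37.53	0.25
1PBVA	195	10	10	0	30.84	0.16	128	10	10	0	30.06	0.15
1PKOA	139	13	3	10	44.12	0.32	58	9	0	9	43.50	0.31
1Q5ZA	177	11	11	0	40.42	0.23	77	6	6	0	46.33	0.26
1RJ1A	151	8	8	0	45.07	0.30	113	7	7	0	41.83	0.28
1T3YA	141	12	6	6	30.33	0.22	83	9	4	5	25.99	0.18
1TP6A	128	9	3	6	32.97	0.26	94	9	3	6	31.72	0.25
1TQGA	105	4	4	0	36.73	0.35	88	4	4	0	38.04	0.36
1TZVA	142	9	9	0	32.42	0.23	97	7	7	0	35.14	0.25
1UAIA	224	18	2	16	57.10	0.25	114	15	0	15	55.64	0.25
1ULRA	88	7	2	5	40.11	0.46	55	7	2	5	36.68	0.42
1VINA	268	16	16	0	51.29	0.19	156	12	12	0	51.04	0.19
1X91A	153	6	6	0	48.33	0.32	113	5	5	0	46.98	0.31
1XAKA	83	7	0	7	30.22	0.36	38	6	0	6	33.08	0.40
1XKRA	206	14	6	8	65.80	0.32	147	14	6	8	66.11	0.32
1XQOA	256	14	14	0	60.32	0.24	162	14	14	0	67.52	0.26
1Z3XA	238	14	14	0	36.63	0.15	129	13	13	0	32.88	0.14
2AP3A	199	7	7	0	53.65	0.27	156	5	5	0	55.95	0.28
2BK8A	97	10	1	9	35.03	0.36	47	7	0	7	30.67	0.32
2CWRA	103	9	0	9	35.71	0.35	60	8	0	8	33.53	0.33
2EJXA	139	10	3	7	41.78	0.30	107	10	3	7	38.38	0.28
2F1SA	186	12	12	0	30.75	0.17	115	12	12	0	35.40	0.19
2FC3A	124	10	6	4	47.78	0.39	80	9	5	4	51.27	0.41
2FM9A	215	10	10	0	58.23	0.27	153	9	9	0	59.69	0.28
2FRGP	106	11	2	9	36.63	0.35	64	9	0	9	33.94	0.32
2GKGA	127	11	6	5	32.56	0.26	80	10	5	5	32.51	0.26
2HUJA	140	4	4	0	50.34	0.36	99	4	4	0	53.84	0.38
2IU1A	208	11	11	0	42.10	0.20	126	10	10	0	43.75	0.21
2JLIA	123	8	4	4	30.25	0.25	69	8	4	4	29.23	0.24
2LISA	136	6	6	0	55.90	0.41	91	5	5	0	53.23	0.39
2OF3A	266	16	16	0	34.76	0.13	202	16	16	0	31.79	0.12
2OSAA	202	11	11	0	49.60	0.25	124	9	9	0	50.70	0.25
2QZQA	152	13	3	10	46.24	0.30	63	7	0	7	52.92	0.35
2R0SA	285	16	16	0	58.40	0.20	165	13	13	0	57.84	0.20
2RB8A	104	8	0	8	33.84	0.33	46	7	0	7	29.12	0.28
2RCIA	204	13	7	6	63.82	0.31	126	10	4	6	63.77	0.31
2V75A	104	5	5	0	32.84	0.32	65	5	5	0	34.26	0.33
2VQ4A	106	10	1	9	33.71	0.32	54	8	0	8	32.07	0.30
2WJ5A	101	7	1	6	31.44	0.31	42	6	0	6	28.26	0.28
2WWEA	127	8	5	3	34.86	0.27	69	7	4	3	35.10	0.28
2YV8A	164	14	1	13	59.67	0.36	79	12	0	12	56.88	0.35
2YXFA	100	9	1	8	32.85	0.33	46	7	0	7	31.37	0.31
2YYOA	171	14	1	13	50.72	0.30	66	12	0	12	58.41	0.34
2ZCOA	293	16	16	0	51.60	0.18	205	15	15	0	56.53	0.19
3B5OA	244	11	11	0	83.49	0.34	169	9	9	0	85.09	0.35
3CTGA	129	11	7	4	33.78	0.26	68	9	5	4	32.00	0.25
3CX2A	108	10	2	8	39.67	0.37	53	7	0	7	37.05	0.34
3FH2A	146	9	9	0	43.06	0.29	100	9	9	0	42.92	0.29
3FHFA	214	13	13	0	51.79	0.24	147	12	12	0	58.19	0.27
3FRRA	191	9	9	0	54.64	0.29	141	9	9	0	55.61	0.29
3HVWA	176	14	7	7	48.29	0.27	109	11	5	6	51.62	0.29
3IV4A	112	11	6	5	35.13	0.31	77	9	4	5	32.98	0.29
3NE3B	130	11	6	5	42.02	0.32	81	9	4	5	48.43	0.37
3OIZA	99	7	3	4	26.73	0.27	63	7	3	4	25.52	0.26
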