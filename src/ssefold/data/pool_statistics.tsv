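pdb_id	psipred_q3	psipred_found	psipred_shift	jufo_q3	jufo_found	jufo_shift	combined_found	combined_shift
1BGCA	88.7	100.0	4.2	81.6	100.0	6.0	100.0	4.2
1EYHA	87.7	100.0	3.5	69.0	87.5	5.3	100.0	3.5
1FQIA	82.2	88.9	1.6	74.8	88.9	4.6	88.9	1.5
1GAKA	87.4	100.0	7.8	68.0	83.3	6.6	100.0	4.5
1GYUA	86.8	100.0	1.1	75.4	100.0	2.1	100.0	0.9
1IAPA	82.1	100.0	6.1	78.8	100.0	5.7	100.0	5.4
1ICXA	84.8	100.0	1.7	76.1	90.0	2.1	100.0	1.6
1J27A	96.2	100.0	0.5	71.3	83.3	2.4	100.0	0.5
1JL1A	75.5	100.0	4.1	66.7	100.0	5.4	100.0	4.0
1LKIA	75.9	80.0	10.3	44.1	80.0	16.8	80.0	10.3
1LMIA	53.7	66.7	2.8	42.5	66.7	3.8	66.7	2.5
1OXJA	83.5	100.0	6.3	76.2	100.0	4.6	100.0	2.3
1OZ9A	91.1	100.0	1.0	79.3	88.9	2.0	100.0	0.8
1PBVA	93.9	100.0	0.8	89.3	100.0	1.4	100.0	0.6
1PKOA	77.1	100.0	1.8	62.8	88.9	2.6	100.0	1.6
1Q5ZA	76.3	100.0	3.2	64.0	100.0	3.8	100.0	1.3
1RJ1A	90.2	100.0	6.0	86.6	100.0	7.4	100.0	5.3
1T3YA	73.0	100.0	2.7	77.8	100.0	2.2	100.0	2.0
1TP6A	75.5	88.9	2.6	58.8	88.9	5.0	88.9	2.6
1TQGA	96.6	100.0	0.8	82.2	100.0	4.0	100.0	0.5
1TZVA	84.8	100.0	6.4	80.0	100.0	7.0	100.0	6.1
1UAIA	68.3	93.3	1.9	64.8	86.7	2.0	100.0	1.5
1ULRA	90.2	100.0	0.9	76.5	100.0	2.3	100.0	0.7
1VINA	83.5	100.0	2.1	71.8	83.3	4.2	100.0	1.8
1X91A	88.6	100.0	2.6	79.2	80.0	4.3	100.0	2.6
1XAKA	51.2	83.3	2.8	27.3	50.0	2.3	83.3	2.8
1XKRA	85.0	92.9	1.5	80.4	85.7	1.2	92.9	1.2
1XQOA	71.8	92.9	4.5	62.5	85.7	4.3	92.9	3.3
1Z3XA	82.6	92.3	1.3	70.6	84.6	7.9	100.0	3.8
2AP3A	81.6	100.0	6.4	76.3	100.0	12.0	100.0	6.0
2BK8A	94.0	100.0	0.4	72.9	100.0	1.9	100.0	0.4
2CWRA	77.4	100.0	2.3	75.8	87.5	1.3	100.0	1.6
2EJXA	71.4	90.0	2.7	47.3	70.0	6.6	90.0	2.7
2F1SA	83.3	91.7	1.5	76.0	83.3	2.1	91.7	1.3
2FC3A	84.4	100.0	1.6	68.7	88.9	3.8	100.0	1.4
2FM9A	85.5	100.0	5.7	85.2	100.0	2.8	100.0	2.6
2FRGP	69.1	88.9	2.1	68.8	88.9	2.5	88.9	2.0
2GKGA	90.0	100.0	0.8	73.6	80.0	1.3	100.0	0.7
2HUJA	94.0	100.0	1.5	83.8	100.0	5.3	100.0	1.5
2IU1A	82.0	90.0	2.7	77.7	90.0	11.4	90.0	2.6
2JLIA	65.2	100.0	3.0	64.4	100.0	4.3	100.0	3.0
2LISA	88.2	100.0	4.6	73.1	100.0	7.4	100.0	4.6
2OF3A	85.4	100.0	7.9	78.2	87.5	5.3	100.0	5.5
2OSAA	79.4	88.9	2.4	70.3	88.9	4.0	88.9	2.1
2QZQA	48.2	85.7	3.8	43.3	85.7	4.5	85.7	3.5
2R0SA	68.6	84.6	2.2	61.3	69.2	3.1	84.6	2.2
2RB8A	80.8	100.0	1.4	82.4	100.0	1.3	100.0	1.0
2RCIA	60.7	90.0	5.3	52.8	90.0	6.3	90.0	4.4
2V75A	76.9	100.0	3.6	72.6	100.0	4.0	100.0	3.2
2VQ4A	74.2	100.0	2.1	71.0	75.0	1.3	100.0	2.0
2WJ5A	83.7	100.0	0.7	73.5	100.0	1.7	100.0	0.8
2WWEA	79.8	100.0	4.3	66.7	71.4	3.2	100.0	4.1
2YV8A	81.2	91.7	1.0	75.3	83.3	1.3	91.7	0.5
2YXFA	69.2	100.0	2.3	55.7	100.0	3.4	100.0	2.1
2YYOA	69.1	100.0	2.2	62.0	100.0	3.0	100.0	2.1
2ZCOA	83.8	93.3	5.7	81.0	100.0	8.3	100.0	5.1
3B5OA	72.3	100.0	9.1	58.6	88.9	8.1	100.0	7.4
3CTGA	83.1	100.0	1.4	67.5	77.8	2.4	100.0	1.4
3CX2A	75.4	100.0	1.3	67.2	100.0	2.4	100.0	1.4
3FH2A	96.0	100.0	0.4	89.4	100.0	3.4	100.0	0.3
3FHFA	68.9	91.7	5.4	63.3	91.7	8.4	100.0	6.7
3FRRA	93.0	88.9	5.4	86.2	88.9	6.5	88.9	5.3
3HVWA	60.0	90.9	3.9	54.6	72.7	4.0	90.9	2.5
3IV4A	83.1	100.0	1.7	81.0	100.0	2.0	100.0	1.3
3NE3B	80.9	100.0	1.3	76.7	100.0	2.3	100.0	1.1
3OIZA	68.0	100.0	3.6	64.5	100.0	3.9	100.0	3.3
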