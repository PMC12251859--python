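trait_class	mqtl_id	chromosome	position_cM	n_qtls	bin	marker_interval	ci_lo_cM	ci_hi_cM	phys_lo_Mb	phys_hi_Mb	contig
PH, EH	MQTL1-1	1	30.90	6	1.01	umc2546-umc1292	5.40	59.20	2.09	5.41	ctg2-ctg3
PH, EH	MQTL1-2	1	130.30	2	1.02	bnlg1178-bnlg1429	125.00	143.50	14.07	16.56	ctg6-ctg7
PH, EH	MQTL1-3	1	232.50	5	1.03	umc1073-bnlg1203	208.60	259.30	32.87	43.71	ctg11
EH	MQTL1-4	1	402.70	2	1.04	bnlg2295-umc1243	398.20	405.00	80.17	83.54	ctg20
PH	MQTL1-5	1	488.10	3	1.05-1.06	umc1603-umc1972	475.90	503.30	165.42	178.04	ctg33-ctg38
PH, EH	MQTL1-6	1	779.40	4	1.08	bnlg1643-umc1991	768.50	800.70	232.80	245.37	ctg50
PH, EH	MQTL2-1	2	54.90	4	2.01-2.02	umc1542-umc1227	54.50	55.30	4.67	4.71	ctg69
PH, EH	MQTL2-2	2	89.10	5	2.02	umc1961-mmc0111	88.90	90.20	8.02	8.30	ctg70
PH, EH	MQTL2-3	2	404.00	3	2.07	bnlg1329-umc2129	383.50	403.40	184.75	188.81	ctg98
PH, EH	MQTL3-1	3	108.40	6	3.02-3.04	bnlg1647-bnlg1904	102.50	126.50	8.21	9.81	ctg112
PH, EH	MQTL3-2	3	193.90	10	3.04	umc1655-umc1504	189.90	227.40	26.31	58.49	ctg116-ctg119
PH, EH	MQTL3-3	3	350.10	8	3.04-3.05	umc1839-umc1087	343.50	364.60	155.29	161.90	ctg117-ctg131
PH, EH	MQTL3-4	3	474.70	3	3.06	umc1644-umc2269	472.30	478.00	183.94	184.73	ctg132-ctg138
PH, EH	MQTL3-5	3	567.20	7	3.07	umc1489-umc1286	566.80	569.60	202.17	202.87	ctg142-ctg143
PH, EH	MQTL3-6	3	803.50	3	3.09-3.10	umc1052-umc2048	789.00	817.20	226.86	230.27	ctg151-ctg151
EH	MQTL4-1	4	312.70	8	4.06	bnlg1741-bnlg1784	296.60	336.30	154.65	170.00	ctg182-ctg431
EH	MQTL4-2	4	535.10	4	4.09	umc1940-umc1650	524.30	544.60	221.18	230.89	ctg196-ctg200
PH, EH	MQTL5-1	5	586.90	9	5.06-5.07	umc2305-bnlg1346	459.20	534.40	193.36	208.04	ctg247-ctg251
EH	MQTL6-1	6	307.00	3	6.05	npi252-bnlg1702	304.00	312.70	143.66	145.85	ctg281-ctg285
PH, EH	MQTL7-1	7	187.20	6	7.02	umc1666-umc1932	181.10	202.50	47.95	78.03	ctg301-ctg308
PH, EH	MQTL7-2	7	401.80	5	7.03-7.04	umc2329-bnlg1666	382.10	428.20	151.28	158.98	ctg322-ctg323
EH	MQTL8-1	8	264.90	3	8.03-8.04	umc1457-umc1858	257.80	285.60	101.65	112.06	ctg345-ctg349
PH, EH	MQTL8-2	8	348.40	3	8.05	bnlg666-umc2210	340.20	366.30	133.37	152.00	ctg354-ctg358
PH	MQTL8-3	8	505.00	3	8.07-8.08	umc1384-bnlg1056	482.40	523.60	169.21	171.33	ctg363-ctg365
PH, EH	MQTL9-1	9	254.10	3	9.03-9.04	bnlg1626-bnlg1209	230.20	268.20	88.14	109.64	ctg376
PH, EH	MQTL10-1	10	68.70	7	10.01-10.02	umc1319-umc1432	47.40	91.40	4.61	5.77	ctg392
PH	MQTL10-2	10	144.90	2	10.03	umc1863-bnlg210	139.40	166.80	13.34	26.78	ctg394-ctg398
PH, EH	MQTL10-3	10	200.40	3	10.03-10.04	bnlg1079-umc1938	196.70	204.50	63.83	77.35	ctg400-ctg402
EH	MQTL10-4	10	232.10	2	10.03-10.04	umc2348-umc1077	229.40	236.90	93.28	102.71	ctg409-ctg411
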