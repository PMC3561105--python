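functional_category	locus	annotation	fi_quartet	fi_pif3_lof	fi_pif145_gof	fi_direct_pif3	category	rapid_light_repression	reciprocal_regulation
Transcription	AT2G46970	PIL1/bHLH124	97.58	1.52	17.71	65.55	Class Z	Not ATH1	Class M
Transcription	AT5G54470	BBX29	21.04	1.01	7.20	21.19	Class Z
Transcription	AT1G02340	HFR1/bHLH26	24.56	1.39	4.41	18.00	Class Z
Transcription	AT3G21330	bHLH87	3.09	1.17	2.07	2.69	Class Z	Not ATH1
Transcription	AT4G16780	ATHB-2	7.36	1.25	2.06	5.98	Class YZ1.5	Class 7	Class M
Transcription	AT3G61830	ARF18	3.59	1.33	2.03	2.75	Class YZ1.5	Class 7
Transcription	AT4G27310	BBX28	2.93	1.28	2.00	2.33	Class YZ1.5	Not ATH1
Transcription	AT5G53980	ATHB52	3.72	1.20	1.92	3.15	Class YZ1.5	Class 7	Class M
Transcription	AT4G32280	IAA29	6.43	1.03	1.91	6.35	Class YZ1.5	Class 7	Class M
Transcription	AT4G01250	WRKY22	2.62	1.18	1.80	2.25	Class YZ1.5
Transcription	AT2G42870	PAR1/HLH1	2.01	0.96	1.69	2.13	Class YZ1.5
Transcription	AT1G69690	TCP15	2.53	1.06	1.66	2.43	Class YZ1.5	Class 7	Class M
Transcription	AT3G25730	EDF3	4.01	1.61	1.66	2.53	Class YZ1.5	Class 7
Transcription	AT3G15540	IAA19/MSG2	3.21	1.15	1.66	2.84	Class YZ1.5	Class 7	Class M
Transcription	AT1G77200	AP2-EREBP family	2.96	1.28	1.66	2.36	Class YZ1.5	Class 7
Transcription	AT3G62090	PIF6/PIL2/bHLH132	13.38	1.15	1.51	11.79	Class YZ1.5	Class 7
Stress/Defense	AT2G33380	RD20/CLO3	25.22	1.96	15.47	13.07	Class Z
Stress/Defense	AT5G63650	SNRK2.5	6.72	1.23	3.62	5.53	Class Z	Class 7	Class M
Stress/Defense	AT4G36010	Thaumatin family	3.74	1.30	1.83	2.91	Class YZ1.5	Class 7	Class M
Signaling	AT3G48260	WNK3	8.54	1.28	3.33	6.78	Class Z	Not ATH1
Photosynthesis	AT1G34630	Tim17/22/23 family	3.31	1.52	1.87	2.22	Class YZ1.5	Class 7
Growth/Development	AT4G14130	XTR7/XTH15	19.37	1.00	6.07	19.66	Class Z	Class 7	Class M
Growth/Development	AT1G67265	RTFL21/DVL3	9.92	1.21	2.71	8.31	Class Z	Not ATH1
Growth/Development	AT1G10550	XTH33	3.11	1.46	2.21	2.16	Class Z	Class 7
Cellular Metabolism	AT5G04120	dPGM-like	9.35	1.53	8.04	6.22	Class Z
Cellular Metabolism	AT4G11050	GH9C3	11.38	1.40	6.90	8.25	Class Z	Class 7
Cellular Metabolism	AT5G51210	OLEO3	6.54	1.54	4.42	4.32	Class Z
Cellular Metabolism	AT2G31980	CYS2	7.85	0.80	3.28	9.92	Class Z	Class 7
Cellular Metabolism	AT5G02540	SDR	12.09	1.40	2.18	8.76	Class YZ1.5	Class 7	Class M
Cellular Metabolism	AT2G34020	Ca-binding EF-hand	2.14	1.04	1.96	2.10	Class YZ1.5	Class 7
Cellular Metabolism	AT5G07010	ST2A	4.80	0.92	1.95	5.32	Class YZ1.5	Class 7
Unknown	AT4G35720	Unknown protein	8.30	1.04	3.98	8.10	Class Z	Class 7	Class M
Unknown	AT5G02580	Unknown protein	4.68	1.01	2.38	4.68	Class Z	Class 7	Class M
Unknown	AT3G17580	Unknown protein	3.94	1.05	2.17	3.82	Class Z	Not ATH1
Non-coding	AT5G26146	Natural antisense	3.08	1.35	2.63	2.33	Class Z	Not ATH1
Non-coding	AT3G17110	Pseudogene	2.97	1.10	2.35	2.74	Class Z
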