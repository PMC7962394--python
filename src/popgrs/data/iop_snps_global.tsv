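rsid	chrom	pos	region	ref	alt	gene	global_eaf	AMR_eaf	AMR_log10p	AFR_eaf	AFR_log10p	EAS_eaf	EAS_log10p	SAS_eaf	SAS_log10p	EUR_eaf	EUR_log10p	KOR_eaf	KOR_log10p
rs1013278	7	117603820	Intergenic	G	C	CTTNBP2;LSM8	0.31	0.28	-0.735	0.33	0.738	0.1	-47.563	0.4	6.676	0.4	7.043	0.114	-102.924
rs10281637	7	116151338	Intergenic	T	C	CAV2;CAV1	0.22	0.21	-0.177	0.4	36.671	0.0089	-80.906	0.19	-1.271	0.26	2.1	0.007	-232.094
rs10483727	14	61072875	Intergenic	T	C	SIX6;SALRNA1	0.35	0.66	51.99	0.034	-146.666	0.21	-17.809	0.42	4.03	0.6	47.063	0.271	-13.494
rs10505100	8	108278616	Intronic	C	A	ANGPT1	0.16	0.18	0.569	0.11	-5.368	0.23	6.644	0.2	2.35	0.11	-4.159	0.283	40.539
rs10918274	1	165714416	Intronic	T	C	TMCO1	0.92	0.87	-3.857	0.92	0.0	0.99	20.362	0.96	5.017	0.86	-7.783	0.993	62.418
rs11217878	11	120340383	Intronic	G	A	ARHGEF12	0.21	0.15	-3.286	0.25	2.601	0.24	1.395	0.23	0.659	0.16	-3.413	0.227	1.147
rs113985657	6	597203	Intronic	C	T	EXOC2	0.12	0.11	-0.249	0.087	-3.132	0.14	1.036	0.12	0.0	0.14	1.014	0.208	26.399
rs11710139	3	15005942	Intergenic	G	A	LINC01214;TSC22D2	0.16	0.14	-0.578	0.16	0.01	0.075	-12.606	0.16	0.0	0.23	6.403	0.096	-16.719
rs12377624	9	129373110	Intergenic	G	C	MVB12B;LMX1B	0.23	0.24	0.194	0.11	-23.178	0.13	-12.549	0.33	9.258	0.37	18.12	0.079	-78.578
rs1254276	14	60847001	Intergenic	C	T	LINC02322;C14orf39	0.63	0.32	-51.921	0.89	82.782	0.78	19.784	0.6	-0.943	0.4	-39.746	0.727	19.784
rs12699251	7	11679113	Intronic	A	G	THSD7A	0.25	0.35	6.518	0.11	-29.965	0.2	-3.064	0.25	0.0	0.4	19.691	0.229	-1.524
rs1579050	2	153364527	Intronic	A	G	FMNL2	0.28	0.46	19.037	0.1	-46.833	0.026	-89.083	0.35	4.372	0.58	69.618	0.025	-242.856
rs17752199	6	51406848	Intergenic	A	G	TFAP2B;PKHD1	0.13	0.13	0.0	0.15	1.166	0.12	-0.364	0.12	-0.327	0.12	-0.32	0.103	-3.773
rs1874458	16	65080739	Intronic	G	A	CDH11	0.2	0.21	0.187	0.085	-24.499	0.21	0.314	0.2	0.0	0.33	17.034	0.25	7.076
rs2022945	8	108251139	Intergenic	A	G	ABRA;ANGPT1	0.84	0.83	-0.204	0.9	7.594	0.77	-6.644	0.8	-2.35	0.89	4.159	0.723	-37.209
rs2024211	7	116153025	Intergenic	A	C	CAV2;CAV1	0.21	0.2	-0.177	0.34	20.57	0.0089	-76.273	0.19	-0.664	0.26	3.118	0.007	-218.926
rs2073006	6	637465	Intronic	C	T	EXOC2	0.11	0.12	0.258	0.045	-13.535	0.15	3.236	0.11	0.0	0.13	1.06	0.22	40.976
rs2188836	7	117635382	Intergenic	C	T	CTTNBP2;LSM8	0.33	0.28	-1.73	0.39	4.233	0.09	-60.936	0.43	7.936	0.41	5.477	0.095	-150.366
rs2317961	6	1533116	Intergenic	A	G	FOXF2;FOXCUT	0.63	0.59	-1.121	0.82	40.735	0.51	-11.567	0.52	-8.961	0.64	0.217	0.475	-44.116
rs2472493	9	107695848	Intergenic	G	A	ABCA1;SLC44A1	0.61	0.65	1.095	0.69	6.97	0.49	-11.416	0.65	1.567	0.58	-1.06	0.46	-40.945
rs2472496	9	107695353	Intergenic	G	A	ABCA1;SLC44A1	0.61	0.64	0.69	0.69	6.97	0.47	-15.152	0.67	3.051	0.58	-1.06	0.428	-59.932
rs2487032	9	107703934	Intergenic	G	A	ABCA1;SLC44A1	0.6	0.48	-7.836	0.83	58.058	0.49	-9.692	0.56	-1.474	0.5	-7.924	0.476	-28.298
rs2745572	6	1548369	Intergenic	A	G	FOXF2;FOXCUT	0.36	0.38	0.395	0.15	-52.096	0.49	13.501	0.48	10.62	0.36	0.0	0.517	45.723
rs28500712	4	7896213	Intronic	A	G	AFAP1	0.66	0.59	-3.016	0.72	4.381	0.68	0.586	0.54	-10.735	0.72	3.416	0.709	5.547
rs28520091	4	7846240	Intronic	C	T	AFAP1	0.32	0.38	2.332	0.15	-36.294	0.29	-1.186	0.37	2.314	0.5	25.369	0.295	-1.77
rs28795989	4	7891545	Intronic	A	G	AFAP1	0.29	0.32	0.743	0.14	-30.033	0.18	-12.655	0.26	-1.084	0.6	73.748	0.17	-36.886
rs2935057	6	170454915	Intergenic	A	G	LINC00574;LOC102724511	0.8	0.82	0.502	0.74	-5.373	0.76	-2.238	0.84	2.252	0.88	8.761	0.729	-13.364
rs3013274	6	170464367	Intergenic	G	A	LINC00574;LOC102724511	0.61	0.58	-0.664	0.7	8.654	0.5	-9.753	0.68	4.063	0.57	-1.606	0.428	-59.784
rs31918	5	14820927	Intronic	C	T	ANKH	0.29	0.34	1.752	0.28	-0.298	0.33	1.881	0.22	-4.799	0.29	0.0	0.334	4.776
rs327716	7	80838977	Intergenic	A	G	SEMA3C;LOC105369146	0.71	0.68	-0.743	0.81	12.896	0.91	45.585	0.64	-4.367	0.43	-60.462	0.947	183.742
rs33912345	14	60976537	Exonic	C	A	SIX6	0.34	0.66	54.967	0.032	-143.37	0.21	-15.632	0.4	3.083	0.6	50.841	0.268	-11.5
rs3785176	16	8896931	Intronic	A	C	PMM2	0.18	0.14	-1.712	0.096	-13.535	0.28	11.463	0.13	-3.575	0.25	6.099	0.316	45.623
rs4141671	10	60338753	Intronic	T	C	BICC1	0.49	0.32	-15.716	0.55	3.871	0.48	-0.226	0.56	3.867	0.49	0.0	0.489	-0.037
rs4236601	7	116162729	Intergenic	G	A	CAV2;CAV1	0.23	0.21	-0.434	0.4	32.449	0.0099	-84.231	0.19	-1.952	0.26	1.262	0.007	-244.996
rs55892100	7	115810676	Intergenic	A	G	TFEC;TES	0.54	0.43	-6.518	0.61	5.149	0.8	54.802	0.43	-8.65	0.37	-21.708	0.835	182.195
rs5756813	22	38175477	Intergenic	G	T	TRIOBP;H1F0	0.55	0.62	2.799	0.4	-21.169	0.71	20.456	0.5	-2.095	0.58	0.989	0.643	16.731
rs58073046	11	120248493	Intronic	A	G	ARHGEF12	0.1	0.042	-6.316	0.013	-32.104	0.17	8.745	0.21	17.513	0.1	0.0	0.168	18.725
rs61394862	5	14851094	Intronic	C	T	ANKH	0.28	0.33	1.781	0.26	-0.777	0.32	1.91	0.21	-4.971	0.28	0.0	0.333	6.636
rs6478746	9	129367398	Intergenic	G	A	MVB12B;LMX1B	0.8	0.85	2.421	0.73	-6.99	0.97	50.342	0.78	-0.668	0.7	-10.654	0.967	127.39
rs66602224	8	108293718	Intronic	G	A	ANGPT1	0.32	0.32	0.0	0.44	14.831	0.14	-32.704	0.28	-1.639	0.4	5.548	0.204	-31.901
rs6732795	2	69411517	Intronic	A	C	ANTXR1	0.66	0.49	-16.002	0.78	16.515	0.85	34.845	0.68	0.54	0.4	-50.841	0.9	152.394
rs73174345	3	169252883	Intronic	T	G	MECOM	0.054	0.036	-1.095	0.13	18.287	0.0	-21.41	0.014	-7.882	0.059	0.23	0.0	-59.854
rs746491	11	86406159	Intergenic	C	A	ME3;PRSS23	0.15	0.17	0.588	0.11	-3.715	0.14	-0.338	0.13	-0.815	0.21	5.097	0.193	6.653
rs7518099	1	165736880	Intronic	C	T	TMCO1	0.92	0.87	-3.857	0.91	-0.608	0.99	20.362	0.96	5.017	0.86	-7.783	0.993	63.362
rs7555523	1	165718979	Intronic	C	A	TMCO1	0.9	0.87	-1.399	0.85	-6.009	0.99	27.97	0.96	9.258	0.86	-3.391	0.993	85.262
rs7924522	11	128380742	Intronic	C	A	ETS1	0.75	0.71	-1.291	0.79	2.503	0.86	14.15	0.75	0.0	0.63	-13.128	0.907	78.316
rs8141433	22	19854006	Intergenic	A	G	GNB1L;TXNRD2	0.28	0.16	-10.572	0.69	159.128	0.037	-78.658	0.22	-3.655	0.15	-18.042	0.04	-200.793
rs9284802	3	85095766	Intronic	G	A	CADM2	0.32	0.33	0.177	0.13	-46.15	0.17	-22.155	0.41	6.585	0.63	72.241	0.176	-49.83
rs945686	9	129378026	Intronic	G	C	LMX1B	0.82	0.87	2.585	0.73	-11.619	0.99	61.221	0.79	-1.348	0.76	-4.495	0.987	156.676
rs9494457	6	136474794	Intronic	T	A	PDE7B	0.39	0.45	2.158	0.37	-0.696	0.33	-3.323	0.44	2.158	0.37	-0.57	0.282	-23.733
rs9853115	3	186131600	Intergenic	T	A	DGKG;LINC02052	0.56	0.47	-4.386	0.48	-6.471	0.73	23.247	0.57	0.193	0.53	-1.014	0.701	38.881
rs9913911	17	10031183	Intronic	A	G	GAS7	0.31	0.32	0.177	0.16	-28.132	0.5	28.572	0.27	-1.662	0.37	3.416	0.554	109.722
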