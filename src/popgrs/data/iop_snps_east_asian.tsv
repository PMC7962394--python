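rsid	chrom	pos	region	ref	alt	gene	eas_eaf	CHS_eaf	CHS_log10p	CDX_eaf	CDX_log10p	KHV_eaf	KHV_log10p	CHB_eaf	CHB_log10p	JPT_eaf	JPT_log10p	KOR_eaf	KOR_log10p
rs1013278	7	117603820	Intergenic	G	C	CTTNBP2;LSM8	0.1	0.105	0.0	0.118	0.162	0.076	-0.079	0.126	0.216	0.087	-0.081	0.114	0.413
rs10281637	7	116151338	Intergenic	T	C	CAV2;CAV1	0.0089	0.005	0.0	0.011	0.061	0.015	0.079	0.015	0.133	0.0	-0.232	0.007	-0.169
rs10483727	14	61072875	Intergenic	T	C	SIX6;SALRNA1	0.21	0.167	-0.381	0.113	-5.663	0.202	-0.034	0.316	4.865	0.26	1.092	0.271	3.218
rs10505100	8	108278616	Intronic	C	A	ANGPT1	0.23	0.233	0.0	0.156	-0.852	0.182	-0.142	0.272	0.285	0.303	0.819	0.283	2.435
rs10918274	1	165714416	Intronic	T	C	TMCO1	0.99	0.976	-0.046	1.0	0.175	0.99	0.0	0.995	0.059	0.995	0.047	0.993	0.229
rs11217878	11	120340383	Intronic	G	A	ARHGEF12	0.24	0.224	0.0	0.339	1.234	0.227	0.0	0.189	-0.328	0.231	-0.023	0.227	-0.229
rs113985657	6	597203	Intronic	C	T	EXOC2	0.14	0.167	0.0	0.097	-0.467	0.086	-0.448	0.189	0.43	0.144	0.004	0.208	4.434
rs11710139	3	15005942	Intergenic	G	A	LINC01214;TSC22D2	0.075	0.071	0.0	0.038	-0.586	0.045	-0.137	0.097	0.195	0.12	0.779	0.096	0.939
rs12377624	9	129373110	Intergenic	G	C	MVB12B;LMX1B	0.13	0.114	0.0	0.14	0.048	0.131	0.0	0.146	0.078	0.125	-0.004	0.079	-4.387
rs1254276	14	60847001	Intergenic	C	T	LINC02322;C14orf39	0.78	0.833	0.126	0.887	1.936	0.778	0.0	0.689	-1.099	0.745	-0.295	0.727	-2.493
rs12699251	7	11679113	Intronic	A	G	THSD7A	0.2	0.224	0.0	0.215	0.061	0.167	-0.079	0.184	-0.059	0.207	0.023	0.229	0.876
rs1579050	2	153364527	Intronic	A	G	FMNL2	0.026	0.01	0.0	0.054	0.658	0.03	0.034	0.029	0.038	0.01	-0.343	0.025	-0.017
rs17752199	6	51406848	Intergenic	A	G	TFAP2B;PKHD1	0.12	0.105	0.0	0.145	0.28	0.106	-0.054	0.112	-0.059	0.115	-0.023	0.103	-0.624
rs1874458	16	65080739	Intronic	G	A	CDH11	0.21	0.229	0.0	0.177	-0.186	0.182	-0.079	0.228	0.078	0.212	0.0	0.25	1.588
rs2022945	8	108251139	Intergenic	A	G	ABRA;ANGPT1	0.77	0.762	0.0	0.828	0.586	0.813	0.096	0.733	-0.195	0.702	-0.779	0.723	-2.027
rs2024211	7	116153025	Intergenic	A	C	CAV2;CAV1	0.0089	0.005	0.0	0.011	0.061	0.015	0.079	0.015	0.133	0.0	-0.232	0.007	-0.169
rs2073006	6	637465	Intronic	C	T	EXOC2	0.15	0.181	0.046	0.118	-0.447	0.081	-2.07	0.189	0.43	0.183	0.44	0.22	4.434
rs2188836	7	117635382	Intergenic	C	T	CTTNBP2;LSM8	0.09	0.076	0.0	0.113	0.182	0.066	-0.079	0.107	0.133	0.091	0.0	0.095	0.098
rs2317961	6	1533116	Intergenic	A	G	FOXF2;FOXCUT	0.51	0.519	0.0	0.5	-0.023	0.495	-0.009	0.549	0.195	0.466	-0.313	0.475	-0.904
rs2472493	9	107695848	Intergenic	G	A	ABCA1;SLC44A1	0.49	0.471	0.0	0.543	0.945	0.455	-0.17	0.519	0.285	0.447	-0.685	0.46	-0.711
rs2472496	9	107695353	Intergenic	G	A	ABCA1;SLC44A1	0.47	0.457	0.0	0.538	0.544	0.449	-0.034	0.485	0.059	0.438	-0.203	0.428	-1.306
rs2487032	9	107703934	Intergenic	G	A	ABCA1;SLC44A1	0.49	0.467	0.0	0.532	0.198	0.449	-0.079	0.51	0.059	0.505	0.047	0.476	-0.209
rs2745572	6	1548369	Intergenic	A	G	FOXF2;FOXCUT	0.49	0.481	0.0	0.505	0.137	0.51	0.079	0.451	-0.43	0.519	0.346	0.517	0.624
rs28500712	4	7896213	Intronic	A	G	AFAP1	0.68	0.695	0.0	0.64	-0.198	0.657	-0.041	0.752	0.489	0.649	-0.191	0.709	0.767
rs28520091	4	7846240	Intronic	C	T	AFAP1	0.29	0.329	0.0	0.328	0.199	0.313	0.041	0.214	-0.598	0.279	-0.025	0.295	0.076
rs28795989	4	7891545	Intronic	A	G	AFAP1	0.18	0.181	0.0	0.156	-0.155	0.187	0.0	0.184	0.035	0.188	0.035	0.17	-0.196
rs2935057	6	170454915	Intergenic	A	G	LINC00574;LOC102724511	0.76	0.7	-0.155	0.774	0.054	0.783	0.054	0.733	-0.133	0.793	0.236	0.729	-0.913
rs3013274	6	170464367	Intergenic	G	A	LINC00574;LOC102724511	0.5	0.419	-0.286	0.565	0.497	0.556	0.142	0.379	-1.458	0.587	0.867	0.428	-3.235
rs31918	5	14820927	Intronic	C	T	ANKH	0.33	0.319	0.0	0.344	0.046	0.298	-0.079	0.316	-0.051	0.375	0.339	0.334	0.054
rs327716	7	80838977	Intergenic	A	G	SEMA3C;LOC105369146	0.91	0.919	0.0	0.909	0.0	0.909	0.0	0.942	0.285	0.904	-0.025	0.947	3.495
rs33912345	14	60976537	Exonic	C	A	SIX6	0.21	0.167	-0.046	0.113	-1.659	0.212	0.0	0.311	1.376	0.255	0.351	0.268	2.976
rs3785176	16	8896931	Intronic	A	C	PMM2	0.28	0.271	0.0	0.296	0.061	0.237	-0.079	0.267	-0.052	0.322	0.329	0.316	1.128
rs4141671	10	60338753	Intronic	T	C	BICC1	0.48	0.443	0.0	0.441	-0.182	0.439	-0.079	0.519	0.195	0.529	0.339	0.489	0.113
rs4236601	7	116162729	Intergenic	G	A	CAV2;CAV1	0.0099	0.005	0.0	0.016	0.172	0.015	0.079	0.015	0.133	0.0	-0.779	0.007	-0.229
rs55892100	7	115810676	Intergenic	A	G	TFEC;TES	0.8	0.805	0.0	0.785	-0.061	0.803	0.0	0.772	-0.133	0.841	0.346	0.835	1.552
rs5756813	22	38175477	Intergenic	G	T	TRIOBP;H1F0	0.71	0.724	0.0	0.849	2.955	0.717	0.0	0.728	0.059	0.529	-4.121	0.643	-3.218
rs58073046	11	120248493	Intronic	A	G	ARHGEF12	0.17	0.167	0.0	0.215	0.447	0.167	0.0	0.155	-0.059	0.159	-0.035	0.168	-0.023
rs61394862	5	14851094	Intronic	C	T	ANKH	0.32	0.319	0.0	0.323	0.0	0.298	-0.041	0.301	-0.059	0.365	0.339	0.333	0.196
rs6478746	9	129367398	Intergenic	G	A	MVB12B;LMX1B	0.97	0.976	0.0	0.946	-0.945	0.944	-0.944	0.971	0.0	0.99	1.2	0.967	-0.106
rs66602224	8	108293718	Intronic	G	A	ANGPT1	0.14	0.167	0.0	0.075	-0.945	0.131	0.0	0.189	0.43	0.144	0.004	0.204	4.208
rs6732795	2	69411517	Intronic	A	C	ANTXR1	0.85	0.819	0.0	0.823	-0.175	0.869	0.04	0.825	-0.133	0.894	0.489	0.9	3.633
rs73174345	3	169252883	Intronic	T	G	MECOM	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs746491	11	86406159	Intergenic	C	A	ME3;PRSS23	0.14	0.129	0.0	0.086	-0.715	0.096	-0.17	0.18	0.285	0.221	1.329	0.193	3.194
rs7518099	1	165736880	Intronic	C	T	TMCO1	0.99	0.976	-0.046	1.0	0.175	0.99	0.0	0.995	0.059	0.995	0.047	0.993	0.229
rs7555523	1	165718979	Intronic	C	A	TMCO1	0.99	0.976	-0.046	1.0	0.175	0.99	0.0	0.995	0.059	0.995	0.047	0.993	0.229
rs7924522	11	128380742	Intronic	C	A	ETS1	0.86	0.876	0.0	0.742	-2.617	0.859	0.0	0.859	0.0	0.933	1.329	0.907	3.495
rs8141433	22	19854006	Intergenic	A	G	GNB1L;TXNRD2	0.037	0.033	0.0	0.022	-0.175	0.02	-0.079	0.029	-0.059	0.077	1.092	0.04	0.113
rs9284802	3	85095766	Intronic	G	A	CADM2	0.17	0.152	0.0	0.134	-0.215	0.172	0.0	0.15	-0.099	0.255	1.296	0.176	0.106
rs945686	9	129378026	Intronic	G	C	LMX1B	0.99	0.995	0.0	0.989	0.0	0.98	-0.079	0.99	0.0	1.0	0.339	0.987	-0.169
rs9494457	6	136474794	Intronic	T	A	PDE7B	0.33	0.262	-0.381	0.328	0.0	0.439	2.084	0.34	0.051	0.284	-0.53	0.282	-1.983
rs9853115	3	186131600	Intergenic	T	A	DGKG;LINC02052	0.73	0.752	0.0	0.753	0.169	0.753	0.079	0.757	0.195	0.654	-1.329	0.701	-0.768
rs9913911	17	10031183	Intronic	A	G	GAS7	0.5	0.519	0.0	0.522	0.175	0.414	-2.084	0.466	-0.285	0.572	1.376	0.554	2.055
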