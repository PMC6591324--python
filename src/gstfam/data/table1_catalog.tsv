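gene_name	locus_id	cds_start	cds_end	strand	gene_len_bp	protein_len_aa	mw_kda	pi	localization
CaGSTU1	Capana00g001895	438859152	438859976	+	825	229	26.25	6.14	Cya,b
CaGSTU2	Capana00g002164	455860084	455861271	+	1188	225	26.00	5.53	Cya,b
CaGSTU3	Capana00g003105	524690584	524692284	-	1701	203	23.67	8.46	Cya,b
CaGSTU4	Capana00g003106	524702849	524704044	-	1196	219	25.56	6.60	Cya,b
CaGSTU5	Capana00g004478	647297751	647300086	-	2336	221	25.12	5.21	Cya, Cpb
CaGSTU6	Capana00g004596	657125404	657128170	+	2767	222	25.73	5.59	Cya, Cyb
CaGSTU7	Capana00g004598	657374139	657375389	-	1251	220	25.34	5.75	Cya,b
CaGSTU8	Capana00g004621	659428697	659429026	+	330	109	12.84	6.97	Cya,b, Mta, Cpa
CaGSTU9	Capana00g004665	665401358	665402749	-	1392	224	25.87	5.57	Cya, Cpb
CaGSTU10	Capana01g002551	166700570	166702635	+	2066	221	25.08	5.08	Cya, Nub
CaGSTU11	Capana01g003292	222778803	222779584	-	782	225	25.63	6.33	Cya,b
CaGSTU12	Capana01g003296	222806252	222809195	-	2944	222	25.91	6.00	Cya,b
CaGSTU13	Capana02g000947	103858121	103858901	-	781	153	17.40	5.57	Cya,b
CaGSTU14	Capana02g000948	103899028	103899345	-	318	105	11.98	9.13	Cya, Cpa, Nub
CaGSTU15	Capana02g000950	104101699	104102578	+	880	225	26.05	5.36	Cya, Cpb
CaGSTU16	Capana02g000952	104250329	104251764	+	1436	224	25.67	5.40	Cya,b
CaGSTU17	Capana03g000768	11322594	11323373	-	780	212	24.43	5.44	Cya, Cpb
CaGSTU18	Capana03g000769	11362575	11363976	-	1402	233	27.12	5.29	Cya,b
CaGSTU19	Capana03g004402	253298052	253300358	+	2307	222	25.91	5.00	Cya
CaGSTU20	Capana03g004562	257827721	257828950	-	1230	225	25.75	6.10	Cya,b
CaGSTU21	Capana03g004565	258031244	258032469	+	1226	225	26.05	6.25	Cya,b
CaGSTU22	Capana03g004566	258056794	258057997	+	1204	225	25.93	7.02	Cya,b
CaGSTU23	Capana06g002861	210286274	210287439	-	1166	220	25.36	5.53	Cya,b
CaGSTU24	Capana07g002003	210859245	210865929	+	6685	220	25.49	5.89	Cya,b
CaGSTU25	Capana07g002004	210867066	210867991	+	926	222	25.60	5.79	Cya,b
CaGSTU26	Capana07g002005	210902595	210903564	+	970	175	20.42	6.84	Cya,b, Cpa
CaGSTU27	Capana07g002006	210941269	210948401	+	7133	282	32.96	8.35	Cya,b
CaGSTU28	Capana07g002007	210981175	210982949	+	630	209	24.34	8.08	Cya,b
CaGSTU29	Capana07g002008	211057582	211057887	+	306	101	11.62	5.14	Cya,b
CaGSTU30	Capana07g002009	211066612	211068955	+	2344	238	27.61	6.25	Cya,b
CaGSTU31	Capana07g002010	211152285	211153567	+	1223	220	25.54	5.78	Cya,b
CaGSTU32	Capana07g002011	211155192	211156505	-	1314	219	25.32	6.84	Cya,b
CaGSTU33	Capana07g002012	211160558	211161672	-	1115	203	23.75	7.00	Cya,b
CaGSTU34	Capana08g001515	132057487	132058584	+	1098	226	25.76	5.38	Cya,b
CaGSTU35	Capana08g001518	132082843	132083882	+	1040	202	22.88	5.36	Cya, Cpa
CaGSTU36	Capana08g001520	132086808	132087750	+	943	181	20.61	5.11	Cya,b, Cpa
CaGSTU37	Capana09g001740	199536703	199537891	+	1189	223	25.30	5.30	Cya, Cpb
CaGSTU38	Capana09g001741	200130618	200131846	+	1229	220	25.04	5.48	Cya, Cpb
CaGSTU39	Capana09g001742	200167723	200169649	+	1927	224	26.36	6.77	Cya, Nub
CaGSTU40	Capana09g001760	202017261	202018643	+	1383	217	25.05	5.28	Cya,b
CaGSTU41	Capana09g001761	202086834	202088344	+	1511	220	24.85	5.41	Cya, Cpb
CaGSTU42	Capana09g001762	202236152	202237088	+	937	220	25.45	5.12	Cya, Cpb
CaGSTU43	Capana09g001763	202238222	202239079	+	858	154	17.67	5.12	Cya, Mta
CaGSTU44	Capana09g001764	202383049	202384214	+	1166	220	25.38	5.53	Cya,b
CaGSTU45	Capana09g001858	213200912	213201949	+	1038	217	25.28	5.38	Cya, Cpb
CaGSTU46	Capana09g001859	213228499	213229454	-	956	219	24.86	5.87	Cya,b
CaGSTU47	Capana09g001860	213238117	213239430	-	1314	221	25.19	5.23	Cya, Nub
CaGSTU48	Capana09g001861	213240773	213241709	+	937	224	25.76	5.58	Cya, Cpb
CaGSTU49	Capana09g001862	213303661	213304284	+	624	143	16.62	4.84	Cya, Mta
CaGSTU50	Capana09g002045	226590245	226590574	+	330	109	13.06	8.78	Cya,b, Mta
CaGSTU51	Capana11g001524	178109400	178111728	+	2329	231	25.76	6.18	Cya, Cpa,b
CaGSTU52	Capana11g001525	178112748	178114176	+	1429	215	23.85	8.88	Cya, Cpa,b
CaGSTU53	Capana11g001528	178187645	178188768	+	1124	220	24.84	6.75	Cya, Cpa,b
CaGSTU54	Capana11g001532	178455711	178456697	+	987	229	26.20	6.76	Cya, Cpb
CaGSTU55	Capana11g001533	178457971	178458582	+	612	203	23.42	6.31	Pma, Ecb
CaGSTU56	Capana11g001535	178483866	178484900	+	1035	229	26.01	5.57	Cya, Cpb
CaGSTU57	Capana11g001536	178558594	178560496	-	1903	229	26.25	5.45	Cya, Cpb
CaGSTU58	Capana11g001537	178588610	178590596	+	1987	229	26.13	5.62	Cya, Cpb
CaGSTU59	Capana12g000354	7186608	7188114	+	1507	219	25.57	5.47	Cya, Nub
CaGSTF1	Capana02g002285	142882377	142883807	+	1431	228	26.02	6.09	Cya, Cpb
CaGSTF2	Capana03g003600	230428836	230430376	+	1541	213	24.19	5.69	Cya, Cpb
CaGSTF3	Capana06g003058	218203021	218205366	+	2346	213	23.76	6.39	Cya, Cpb
CaGSTF4	Capana06g001819	54683346	54684364	-	1019	251	29.29	8.68	Cya,b, Mta, Nua
CaGSTF5	Capana12g000609	14792240	14802489	+	10250	654	74.94	7.13	Pma, Cyb
CaGSTF6	Capana12g000612	14873894	14878274	+	4381	252	28.64	5.26	Cya, Eca, Cpb
CaGSTT1	Capana01g000218	3161948	3164992	+	3045	186	21.15	9.74	Mta, Nua, Cyb
CaGSTT2	Capana01g000219	3169497	3173899	+	4403	250	28.34	9.25	Cya, Mta, Nua
CaGSTT3	Capana01g000221	3200545	3205818	+	5274	241	27.33	9.26	Cya,b, Mta
CaGSTT4	Capana12g001178	52439179	52442473	-	3295	235	26.46	6.45	Cya, Cpb
CaGSTZ1	Capana01g001395	45340308	45347371	-	7064	283	32.48	8.34	Mta, Cya, Cpb,c
CaGSTZ2	Capana12g000896	32868383	32869334	+	952	107	12.47	5.01	Pma, Cyb
CaGSTL1	Capana05g000544	14609977	14614464	+	4488	314	35.45	8.71	Cpa,b,c
CaGSTL2	Capana09g001864	213395287	213400333	+	5047	239	27.75	5.57	Cya,b
CaGSTL3	Capana10g001792	183887466	183889739	-	2274	222	25.80	5.24	Cya,b
CaGSTL4	Capana10g001806	186021678	186025506	-	3829	253	29.10	5.75	Cya,b, Mta
CaEF1Bg1	Capana11g000124	3480968	3485480	-	4513	414	46.83	5.65	Cya, Cpb
CaEF1Bg2	Capana08g000330	43923121	43924032	-	912	204	23.47	8.67	Cya, Nua
CaDHAR1	Capana05g000799	31400365	31405449	+	5085	295	32.75	8.33	Mta, Cpa,b,c
CaDHAR2	Capana05g002401	214455819	214460536	-	4718	212	23.57	5.88	Cya,b
CaTCHQD	Capana00g004998	686182991	686184172	+	1182	268	31.64	9.06	Mta, Cya
CaMGST1	Capana02g002296	143033395	143035039	+	1645	144	16.38	9.15	Pma
CaMGST2	Capana04g000166	2049728	2054459	-	4732	323	36.21	9.02	Cpa,c
CaGHR1	Capana02g001236	116162258	116176687	+	14430	361	41.43	6.80	Mta, Nua, Cpc
CaGHR2	Capana02g000926	102853919	102854627	-	709	123	13.73	4.37	Nua, Cya
CaGHR3	Capana06g000146	1927452	1929409	+	1958	373	41.82	6.61	Cpa,c
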