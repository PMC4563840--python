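name	gene_id	species	chromosome	start	end	orf_bp	length_aa	pi	mol_wt_da	exons
PtrWRKY41	Potri.001G092900.1	Ptr	1	7326486	7329009	1017	338	6.1	38600.47	3
PtrWRKY63	Potri.002G168700.1	Ptr	2	12778165	12781030	1092	363	6.04	41572.99	3
PtrWRKY53	Potri.003G138600.1	Ptr	3	15656901	15658916	1029	342	5.46	39024.98	3
PtrWRKY89	Potri.006G109100.1	Ptr	6	8522038	8524071	1002	333	6.24	38321.26	3
PtrWRKY30	Potri.012G031700.1	Ptr	12	2820069	2822264	1116	371	5.81	41993.43	3
PtrWRKY90	Potri.013G090400.1	Ptr	13	9549330	9551441	1059	352	5.97	39666.24	3
PtrWRKY54	Potri.013G090300.1	Ptr	13	9541636	9543313	975	324	5.48	37325.53	3
PtrWRKY64	Potri.014G096200.1	Ptr	14	7526597	7529192	1098	365	5.23	41813.27	3
PtrWRKY62	Potri.016G137900.1	Ptr	16	14049379	14051741	966	321	6.06	36678.63	3
PtrWRKY55	Potri.019G059300.1	Ptr	19	9106420	9108112	756	351	7.82	27324.05	3
VvWRKY6	GSVIVT01019511001	Vv	2	1228314	1229702	1029	342	6.05	38561.86	3
VvWRKY27	GSVIVT01030174001	Vv	8	10843756	10846082	996	331	5.76	37484.73	5
VvWRKY41	GSVIVT01032662001	Vv	13	1716836	1718836	927	308	6.72	34255.17	4
VvWRKY42	GSVIVT01032661001	Vv	13	1719393	1720884	867	288	5.71	32693.34	4
VvWRKY48	GSVIVT01027069001	Vv	15	18191021	18193489	1083	360	5.16	40234	5
VvWRKY52	GSVIVT01028718001	Vv	16	19477141	19479868	1095	364	5.45	40043.4	3
AtWRKY30	AT5G24110.1	At	5	8153115	8154709	912	303	6.11	33985.32	3
AtWRKY38	AT5G22570.1	At	5	7495539	7496784	870	289	5.4	33268.25	3
AtWRKY41	AT4G11070.1	At	4	6759303	6760794	942	313	9.23	34894.21	3
AtWRKY46	AT2G46400.1	At	2	19043414	19044826	888	295	5.73	33634.72	3
AtWRKY53	AT4G23810.1	At	4	12392370	12393982	975	324	6.34	36272.58	2
AtWRKY54	AT2G40750.1	At	2	17000454	17002468	1041	346	5.23	38645.28	3
AtWRKY55	AT2G40740.1	At	2	16997177	16999277	879	292	7.69	32488.79	3
AtWRKY62	AT5G01900.1	At	5	351008	352069	792	263	5.91	30442.52	2
AtWRKY63	AT1G66600.1	At	1	24848320	24849364	726	241	5.63	27378.84	3
AtWRKY64	AT1G66560.1	At	1	24833579	24834631	750	249	4.89	28549.92	3
AtWRKY66	AT1G80590.1	At	1	30296210	30297156	708	235	5.8	26402.81	3
AtWRKY67	AT1G66550.1	At	1	24828537	24829589	765	254	6.34	29039.72	3
AtWRKY70	AT3G56400.1	At	3	20908928	20910481	885	294	5.85	32935.64	3
OsWRKY77	LOC_Os01g40260.1	Os	1	22731943	22733240	741	246	5.05	59691.44	3
OsWRKY11	LOC_Os01g43650.1	Os	1	25009453	25012236	1140	379	4.97	92538.29	3
OsWRKY17	LOC_Os01g74140.1	Os	1	42946753	42948750	1233	410	4.96	101998.04	3
OsWRKY20	LOC_Os01g60540.1	Os	1	35008866	35011098	1128	375	4.99	90787.21	3
OsWRKY21	LOC_Os01g60640.1	Os	1	35062734	35064940	843	280	5.03	67914.43	2
OsWRKY32	LOC_Os02g53100.1	Os	2	32489017	32495070	1815	604	4.88	145142.97	6
OsWRKY55	LOC_Os03g20550.1	Os	3	11650824	11652144	633	210	5.14	52608.57	3
OsWRKY80	LOC_Os03g63810.1	Os	3	36039164	36043822	1164	387	4.96	97006.11	3
OsWRKY68	LOC_Os04g51560.1	Os	4	30545175	30546577	930	309	4.96	78001.61	3
OsWRKY5	LOC_Os05g04640.1	Os	5	2179520	2184940	1509	502	4.89	122971.29	6
OsWRKY53	LOC_Os05g27730.1	Os	5	16150266	16152747	1464	487	4.89	119588.82	5
OsWRKY48	LOC_Os05g40060.1	Os	5	23529423	23530499	996	331	5	80700.18	2
OsWRKY84	LOC_Os05g40070.1	Os	5	23536113	23539013	843	280	5.06	68885.55	3
OsWRKY54	LOC_Os05g40080.1	Os	5	23550611	23551716	987	328	5.01	80020.28	2
OsWRKY49	LOC_Os05g49100.1	Os	5	28154693	28157989	1260	419	4.95	101051.58	3
OsWRKY19	LOC_Os05g49620.1	Os	5	28471802	28473061	834	277	5.04	67350.85	3
OsWRKY31	LOC_Os06g30860.1	Os	6	17915923	17917083	1041	346	4.97	84041.8	2
OsWRKY87	LOC_Os07g39480.1	Os	7	23654076	23659625	1857	618	4.93	152671	6
OsWRKY88	LOC_Os07g40570.1	Os	7	24311898	24315383	1299	432	5	106573.1	4
OsWRKY89	LOC_Os08g17400.1	Os	8	10633195	10639603	1653	550	4.99	130711.96	4
OsWRKY69	LOC_Os08g29660.1	Os	8	18220041	18222408	960	319	4.97	78415.14	2
OsWRKY90	LOC_Os09g30400.3	Os	9	18496949	18500579	1902	633	4.91	157640.64	5
OsWRKY18	LOC_Os10g18099.1	Os	10	9184625	9192018	831	276	5.04	68355.38	3
OsWRKY72	LOC_Os11g29870.1	Os	11	17352085	17355820	729	242	5.06	59599.38	2
OsWRKY97	LOC_Os12g02420.1	Os	12	802489	806097	675	224	5.09	56271.46	3
OsWRKY64	LOC_Os12g02450.1	Os	12	824302	825793	966	321	5.04	79376.04	3
OsWRKY96	LOC_Os12g32250.1	Os	12	19473728	19478606	1623	540	4.93	133380.3	6
OsWRKY94	LOC_Os12g40570.1	Os	12	25100479	25104175	1098	365	5.03	87261.58	4
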