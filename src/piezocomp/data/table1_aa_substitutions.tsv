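aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	20257	374	609	1124	212	1565	182	567	734	696	314	317	690	501	493	2167	1283	1389	52	103
C	417	3674	45	40	84	95	30	89	42	139	68	59	33	30	82	260	175	212	14	44
D	708	33	13857	2843	58	755	227	89	624	119	72	1054	345	446	296	759	554	140	9	42
E	1543	51	3217	16624	66	713	296	213	1362	331	160	563	529	1244	738	983	896	416	21	58
F	217	64	36	67	11404	86	186	487	52	1400	289	63	65	76	76	169	170	372	151	1264
G	1509	121	741	612	62	24896	144	105	425	164	75	498	221	233	333	897	352	173	19	40
H	170	26	142	209	155	88	4823	69	189	145	55	240	79	288	282	191	154	87	28	307
I	527	97	72	169	494	89	67	14289	166	3471	774	79	113	126	169	172	523	4167	47	130
K	989	57	725	1452	96	556	353	229	12658	426	233	713	392	1253	2689	877	1001	401	28	84
L	641	164	120	280	1225	161	174	2854	286	27777	1943	103	219	329	356	258	505	2010	142	297
M	293	56	79	141	275	72	67	740	191	2146	6418	79	57	185	152	145	243	547	46	89
N	491	54	1090	629	63	596	366	108	685	158	80	7465	161	419	429	881	581	133	13	107
P	717	32	264	406	55	212	89	115	283	254	56	109	13594	195	165	499	298	201	23	32
Q	436	29	419	1057	59	221	308	108	805	358	167	274	177	6142	668	400	367	180	25	58
R	437	67	257	495	73	293	333	137	1969	304	132	261	164	617	13408	433	373	172	65	89
S	2729	234	813	807	114	1033	260	197	703	318	157	743	515	450	534	11048	1915	369	29	90
T	1138	153	379	571	128	290	144	461	530	469	255	397	294	318	376	1630	11069	810	29	63
V	1541	225	115	320	364	187	82	4079	271	2081	638	107	209	182	211	365	946	17069	39	122
W	35	12	8	18	122	22	34	39	18	95	31	9	12	17	42	24	26	34	3310	117
Y	140	50	65	81	1381	46	371	132	71	311	97	98	50	83	94	139	100	129	169	7621
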