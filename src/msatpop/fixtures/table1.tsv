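pop	location	lat	lon	N	Na	Ne	I	Ho	He	PPL	FIS	Qp
LD	Luding, Sichuan	29.57	102.02	19	4.824	2.972	1.083	0.383	0.533	94.12	0.306	0.95
WN	Weining, Guizhou	26.86	104.28	20	5.176	2.833	1.044	0.350	0.497	94.12	0.319	0.95
LC	Enshilichuan, Hubei	30.27	108.70	20	5.706	3.606	1.278	0.444	0.609	94.12	0.296	0.95
SM	Shimen, Hunan	29.94	110.78	20	6.176	3.878	1.312	0.370	0.601	94.12	0.406	0.80
WG	Wugang, Henan	33.33	113.54	20	4.941	3.123	1.108	0.341	0.548	88.24	0.400	0.95
BJ	Baojing, Hunan	28.60	109.49	20	6.412	3.771	1.317	0.400	0.604	94.12	0.361	0.70
LL	Longlin, Guangxi	24.79	105.03	16	5.529	3.959	1.288	0.419	0.609	94.12	0.341	0.56
GY	Guiyang, Guizhou	26.61	106.69	20	6.176	3.780	1.289	0.380	0.591	94.12	0.379	0.10
XY	Xinayang, Henan	31.83	114.08	20	5.294	3.390	1.189	0.367	0.570	100.00	0.378	0.60
WY	Wanyuan, Sichuan	31.80	107.68	12	4.176	2.527	0.954	0.329	0.482	88.24	0.356	0.75
JY	Jinyun, Sichuan	29.83	106.40	17	5.294	3.086	1.160	0.349	0.562	94.12	0.407	0.47
HH	Huaihua, Hunan	27.56	109.96	20	6.000	3.615	1.236	0.384	0.574	100.00	0.355	0.80
SN	Suining, Hunan	26.42	110.06	6	3.353	2.609	0.902	0.373	0.484	82.35	0.314	1
DK	Hongjiangdongkou, Hunan	27.13	110.56	17	5.529	3.285	1.139	0.397	0.525	94.12	0.273	0.88
HCS	Changsha, Hunan	28.18	112.93	17	6.118	3.617	1.207	0.360	0.538	94.12	0.357	0.88
PX	Pingxiang, Jiangxi	27.84	113.89	20	6.353	3.490	1.186	0.339	0.528	100.00	0.380	0.95
YF	Yifeng, Jiangxi	28.48	114.55	9	4.471	2.904	1.015	0.373	0.494	94.12	0.300	1
YX	Yongxiu, Jiangxi	29.10	115.59	18	5.706	3.313	1.161	0.344	0.538	94.12	0.386	0.89
JJ	Jiujiang, Jiangxi	29.61	115.91	21	6.235	3.519	1.191	0.454	0.541	100.00	0.185	1
ST	Shitai, Anhui	30.21	117.49	16	6.176	3.919	1.239	0.441	0.555	94.12	0.236	0.94
DX	Dexing, Jiangxi	28.93	117.72	19	5.059	3.251	1.058	0.380	0.499	94.12	0.261	1
SR	Shangrao, Jiangxi	28.45	117.98	8	4.765	3.147	1.100	0.390	0.532	88.24	0.328	1
SW	Shaowu, Fujian	27.08	117.27	19	6.118	3.702	1.208	0.410	0.547	94.12	0.277	1
NJ	Nanjiang, Jiangsu	32.08	118.85	15	5.294	3.398	1.172	0.319	0.559	100.00	0.458	0.93
JR	Jurong, Jiangsu	32.13	119.09	20	5.824	3.520	1.175	0.281	0.535	94.12	0.494	0.95
HZ	Hangzhou, Zhejiang	30.28	120.20	8	3.824	2.804	0.949	0.309	0.479	94.12	0.413	0.88
SX	Shaoxing, Zhejiang	29.71	120.23	18	5.706	3.501	1.137	0.383	0.518	94.12	0.287	1
YK	Yongkang, Zhejiang	28.88	120.03	19	5.294	3.105	1.069	0.312	0.495	94.12	0.393	1
JCS	Changshu, Jiangsu	31.66	120.72	16	5.353	3.372	1.203	0.365	0.575	94.12	0.393	0.81
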