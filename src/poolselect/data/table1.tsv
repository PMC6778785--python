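strain	n_unique_snvs	avg_coverage	se_coverage	trait_value
AB1	22	1910	132.1	-0.001089558
AB4	43	812	51.8	-0.000735581
CB4851	22	1800	165.7	-1.28E-05
CB4852	16	1564	133.9	-9.77E-05
CB4853	22	1527	114.5	-0.000104916
CB4854	182	1829	74.7	-0.000834588
CB4856	874	1915	32.6	-0.000926858
CB4857	47	1317	90.2	-0.000486995
CB4858	14	1054	92.5	-0.000279677
CB4932	31	1477	105	8.25E-05
CX11262	16	1315	107.1	-0.000776708
CX11264	29	2002	164.5	-0.001023059
CX11271	42	1884	126.2	-0.000285448
CX11285	72	2227	120.1	-0.000454118
CX11292	1	1398	316.6	0.000365799
CX11307	62	8415	2592.2	-0.000483986
CX11314	11	1612	192.5	-0.000528437
CX11315	47	1768	101.7	0.001110572
DL200	23	1446	102.6	0.005747001
DL226	117	2484	296.5	-0.000764146
DL238	966	2561	170.8	-0.000804199
ED3005	14	1789	144.3	0.001394962
ED3011	17	1296	120	-0.000241451
ED3012	16	1434	128	-0.000347688
ED3017	24	1631	129.5	0.002837005
ED3040	43	1749	121.8	-2.54E-05
ED3046	42	1779	123.5	-0.000153265
ED3048	32	1210	113.9	0.000259088
ED3049	2	979	251.8	-0.000428888
ED3052	34	1798	144.1	0.002854565
ED3073	43	1414	83.1	-0.000480596
ED3077	30	1255	75.1	0.015852705
EG4347	8	1732	309.9	0.000265527
EG4349	73	1768	103.7	0.000949259
EG4724	68	1465	72.8	-0.000240064
EG4725	213	2274	74.3	0.000711111
EG4946	25	1577	133.7	-0.001189646
JT11398	67	2661	319	-0.000251866
JU1088	38	1350	89.6	-0.000542719
JU1172	39	1875	133.9	-0.000573628
JU1200	18	1292	109.5	0.000643843
JU1212	67	2601	156.2	-0.000501071
JU1213	47	2065	110.2	0.00010362
JU1242	29	1790	145	-0.000508404
JU1246	19	1109	87.4	-0.000352744
JU1395	14	2068	239.2	-0.000812441
JU1400	66	2271	137	-9.72E-05
JU1409	73	1419	71.7	-0.000496307
JU1440	26	1452	97.7	-0.00046671
JU1491	43	1759	112.5	-0.00018339
JU1530	14	1211	109.1	-0.000394825
JU1568	28	1721	130.7	-9.76E-06
JU1580	28	1586	107.8	0.000636567
JU1581	67	1591	103.4	-0.001178581
JU1586	22	1228	89.8	-0.000505315
JU1652	77	1682	97.2	0.004598108
JU1896	121	1825	69.9	0.001495203
JU258	147	2293	102.4	-0.000978538
JU310	20	1642	133.8	-0.000783759
JU311	25	1678	138.8	-0.000460506
JU323	35	14009	4563.5	-0.000451522
JU346	45	2322	201.2	-0.000320575
JU360	9	1163	145	-0.000889179
JU363	5	1188	168.9	0.000173825
JU367	24	1497	190.5	-0.000317346
JU393	20	1877	179.3	-0.00097683
JU394	27	1700	115	8.55E-05
JU397	21	1291	90.2	-1.14E-05
JU406	19	1466	158.3	7.70E-05
JU440	24	1408	105.4	-0.000588908
JU561	42	1306	72.1	-0.000947311
JU642	27	1418	109.4	-0.000175764
JU751	19	2271	243.7	-0.000343356
JU774	87	2017	120.3	0.000156211
JU775	726	1794	30.7	-0.00013356
JU778	91	1430	54.9	-0.000466356
JU782	100	2863	152.5	-0.000251516
JU792	26	1424	125.5	-0.000126172
JU830	22	1760	187.8	-0.000421824
JU847	33	1529	101.4	0.000694595
KR314	83	1789	73.6	-0.000739883
LKC34	58	1484	82.4	0.000101218
LSJ1	7	1962	341.3	0.000228846
MY1	39	1992	143.8	-0.000355746
MY10	148	3028	106.3	-0.000267622
MY16	41	1743	124.6	-0.001084975
MY18	26	14878	6112.5	0.000116325
MY23	176	1821	68	-0.000536114
PB303	16	1354	143.8	-0.001618959
PB306	220	2071	69.7	-0.000679825
PS2025	99	2002	122	-0.002479676
PX174	46	1302	86.2	-0.000170046
PX179	13	1289	108.7	-0.000586876
QX1211	5355	2407	35.8	-0.000186515
QX1233	53	1493	91.3	-0.000967571
WN2002	65	1442	110.1	-0.000671692
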