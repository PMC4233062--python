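# Cotton Hsf exon-intron structures. Exon coordinates are transcript-relative,
# 1-based inclusive (Exon2 start = Exon1 end + 1); intron lengths (bp) are printed
# separately. Empty intron2/exon3 fields mean the gene has a single intron.
gene	locus	exon1_start	exon1_end	intron1	exon2_start	exon2_end	intron2	exon3_start	exon3_end
GhHsf1	Gorai.001G012700	32	457	593	458	1063
GhHsf2	Gorai.002G135200	1	249	85	250	974	306	975	999
GhHsf3	Gorai.003G023500	50	253	625	254	937
GhHsf4	Gorai.003G053300	136	381	1414	382	1644
GhHsf5	Gorai.003G091700	1	249	1268	250	717
GhHsf6	Gorai.003G160600	147	407	74	408	1079
GhHsf7	Gorai.003G183900	103	411	1314	412	1650
GhHsf8	Gorai.004G076900	154	468	706	469	1242
GhHsf9	Gorai.004G208800	92	349	120	350	1027
GhHsf10	Gorai.004G257000	1	249	1472	250	1512
GhHsf11	Gorai.004G280100	1	213	90	214	984
GhHsf12	Gorai.004G284200	1	282	89	283	1091	84	1092	1491
GhHsf13	Gorai.005G027500	15	263	597	264	1502
GhHsf14	Gorai.005G102000	1	249	151	250	1032
GhHsf15	Gorai.006G087100	1	276	2513	277	576
GhHsf16	Gorai.006G125000	1	237	127	238	777
GhHsf17	Gorai.006G158000	177	503	744	504	1625
GhHsf18	Gorai.006G224000	71	316	607	317	1504
GhHsf19	Gorai.006G242400	1	303	79	304	1023
GhHsf20	Gorai.007G010900	148	402	104	403	1128
GhHsf21	Gorai.007G033300	77	388	2621	389	1516
GhHsf22	Gorai.007G053900	1	366	1399	367	1050
GhHsf23	Gorai.007G139600	1	306	541	307	1038
GhHsf24	Gorai.008G170800	74	292	2270	293	1147
GhHsf25	Gorai.008G225200	282	590	2770	591	1817
GhHsf26	Gorai.008G244400	169	384	111	385	1083
GhHsf27	Gorai.009G024700	85	294	76	295	1136
GhHsf28	Gorai.009G032300	1	525	102	526	1344
GhHsf29	Gorai.009G213100	25	273	123	274	1107
GhHsf30	Gorai.010G020700	1	219	122	220	942
GhHsf31	Gorai.010G070900	171	383	82	384	1193
GhHsf32	Gorai.010G240800	77	292	83	293	1231
GhHsf33	Gorai.011G027400	1	282	1220	283	666
GhHsf34	Gorai.011G036400	1	216	97	217	1212
GhHsf35	Gorai.011G105700	280	483	298	484	1119
GhHsf36	Gorai.011G168400	1	300	511	301	1074
GhHsf37	Gorai.012G044200	234	449	172	450	1418
GhHsf38	Gorai.013G183500	213	461	1886	462	1511
GhHsf39	Gorai.013G220400	33	356	85	357	1175
GhHsf40	Gorai.N013300	8	226	1504	227	1210
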