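# Cotton Hsf family census (D-subgenome): gene, source locus, protein length (aa),
# isoelectric point, molecular weight (Da) and chromosome. Chromosome "N" denotes
# the unanchored linkage group. Genes are numbered by chromosomal position.
gene	locus	length	pi	mw	chromosome
GhHsf1	Gorai.001G012700	343	5.87	40037.16	1
GhHsf2	Gorai.002G135200	332	8.27	37421.34	2
GhHsf3	Gorai.003G023500	295	6.05	32506.19	3
GhHsf4	Gorai.003G053300	502	6.21	55588	3
GhHsf5	Gorai.003G091700	238	8.58	27518.09	3
GhHsf6	Gorai.003G160600	310	5.27	34627.59	3
GhHsf7	Gorai.003G183900	515	4.78	56720.74	3
GhHsf8	Gorai.004G076900	362	5.66	41686.65	4
GhHsf9	Gorai.004G208800	311	5.02	34368.2	4
GhHsf10	Gorai.004G257000	503	5.53	55394.64	4
GhHsf11	Gorai.004G280100	327	6.17	36589.64	4
GhHsf12	Gorai.004G284200	496	5.53	56720.6	4
GhHsf13	Gorai.005G027500	495	5.43	55737.3	5
GhHsf14	Gorai.005G102000	343	8.14	38575.58	5
GhHsf15	Gorai.006G087100	191	7.71	22255.34	6
GhHsf16	Gorai.006G125000	258	9.32	29765.52	6
GhHsf17	Gorai.006G158000	482	4.81	53912.11	6
GhHsf18	Gorai.006G224000	477	5.51	53905.72	6
GhHsf19	Gorai.006G242400	340	5.80	39491.57	6
GhHsf20	Gorai.007G010900	326	6.92	36273.79	7
GhHsf21	Gorai.007G033300	479	4.74	52198.91	7
GhHsf22	Gorai.007G053900	295	7.67	33372.16	7
GhHsf23	Gorai.007G139600	345	5.22	39812.5	7
GhHsf24	Gorai.008G170800	357	4.66	41293.15	8
GhHsf25	Gorai.008G225200	511	5.10	56197.53	8
GhHsf26	Gorai.008G244400	304	5.58	33899.14	8
GhHsf27	Gorai.009G024700	350	5.67	39696.82	9
GhHsf28	Gorai.009G032300	447	4.96	50753.62	9
GhHsf29	Gorai.009G213100	360	8.44	40131.3	9
GhHsf30	Gorai.010G020700	313	6.51	35645.86	10
GhHsf31	Gorai.010G070900	340	5.47	38603.7	10
GhHsf32	Gorai.010G240800	384	5.36	44645.69	10
GhHsf33	Gorai.011G027400	221	8.95	25756.83	11
GhHsf34	Gorai.011G036400	403	5.08	46024.05	11
GhHsf35	Gorai.011G105700	279	6.23	30749.59	11
GhHsf36	Gorai.011G168400	357	5.51	41384.46	11
GhHsf37	Gorai.012G044200	394	5.53	45002.18	12
GhHsf38	Gorai.013G183500	432	5.10	47712.05	13
GhHsf39	Gorai.013G220400	380	4.76	42597.48	13
GhHsf40	Gorai.N013300	379	4.66	43357.61	N
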