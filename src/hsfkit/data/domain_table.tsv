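# Cotton Hsf functional-domain census. dbd and hrab are 1-based inclusive residue
# ranges (hrab may have two segments separated by "/"); linker is the printed
# linker-length column (residues between DBD end and HR-A/B start); nls/nes hold
# "(pos)MOTIF" entries; aha holds one or more "(pos)MOTIF" entries separated by ";".
# Empty fields mean no motif reported.
gene	locus	protein_type	dbd	linker	hrab	nls	nes	aha
GhHsf7	Gorai.003G183900	A1a	41-134	29	163-214	(248)KKRRLK	(501)LTEQMGLL	(457)FWEDLLV
GhHsf4	Gorai.003G053300	A1b	20-113	36	139-177	(224)KKRRLSR	(488)LTEQMGLR	(437)DVFWEQFL
GhHsf25	Gorai.008G225200	A1c	41-134	29	163-216	(248)KKRR	(497)LTEQMGLL	(450)VNSPFFHDLF
GhHsf21	Gorai.007G033300	A1d	42-135	29	164-207	(249)KKRR		(452)DSSSFWDDLI
GhHsf10	Gorai.004G257000	A1e	21-114	26	140-178	(225)KKRR	(489)LTEQMGLL	(437)DVFWEKFL
GhHsf38	Gorai.013G183500	A1f	21-114	23	137-184	(222)KKRRLHR		(401)DTFWEHFL
GhHsf39	Gorai.013G220400	A2	46-139	23	162-213	(243)RKRR	(369)LVDQMGYL	(320)ETLWEELVHEDL
GhHsf17	Gorai.006G158000	A3	47-140	20	160-191	(242)RMRRK		(365)PGYFISSPEDL;(396)DVWSMDFDATV
GhHsf34	Gorai.011G036400	A4a	10-103	14	117-180	(205)RKRR	(390)LAEQMGHL	(339)DIFWEQFLTE
GhHsf37	Gorai.012G044200	A4b	10-103	18	121-175	(198)KKRK		(246)TLFLEIGETIG;(372)GFWERFLTEV
GhHsf32	Gorai.010G240800	A4c	10-103	21	122-174	(205)RKRR	(371)LTEQMGHL	(319)DGFWEQFLTE
GhHsf18	Gorai.006G224000	A5a	20-113	17	130-185	(217)KKRR	(261)LRLELS	(358)SPSLTMMSQL;(426)DVFWERFLTE
GhHsf13	Gorai.005G027500	A5b	21-114	12	126-189	(216)KKRR	(257)LRLELS	(375)SPILTRMSQP;(443)DVFWEQFLTE
GhHsf36	Gorai.011G168400	A6a	38-131	30	161-202	(236)KKRQRR	(345)LVEQLRYL	(270)EVTELDKLVM;(310)DEGFWDDLMDGDTH
GhHsf19	Gorai.006G242400	A6b	39-132	34	156-182/216-243	(238)KRRRR	(328)LVEQLGFL	(264)EVVELDGMVM;(295)DEGFWNDLLND
GhHsf8	Gorai.004G076900	A7a	43-136	36	172-246	(242)KKRRR	(350)LADRLGYL	(219)NPAFLRQLM;(318)DEGFWEELLNE
GhHsf23	Gorai.007G139600	A7b	40-133	32	165-230	(240)RKRMR		(217)NPSFLQQLM;(320)DEGFWEELLNE
GhHsf40	Gorai.N013300	A8a	1-83	37	120-142	(188)KENNWR	(361)LTDQMGHL	(253)DFWMNIDFVKV;(279)DDGAWEKLLL
GhHsf24	Gorai.008G170800	A8b	11-104	35	139-161	(103)RRK		(267)DFWMDIDFVKA;(293)DDGAWEKLL
GhHsf28	Gorai.009G032300	A9a	113-206	24	230-269	(294)RLTKKRK	(418)IYLELEDL	(429)KQCSWGGFASEL
GhHsf1	Gorai.001G012700	A9b	80-173	22	195-240	(274)KKFKKRRR	(329)IYVELKQL
GhHsf12	Gorai.004G284200	A9c	32-125	22	137-214	(253)RKKRR	(468)VYLELEDL	(479)KPSNLTGFVNDL
GhHsf3	Gorai.003G023500	B1a	6-99	53	152-195	(258)KKRAR
GhHsf22	Gorai.007G053900	B1b	6-99	44	143-189	(257)KKR
GhHsf35	Gorai.011G105700	B1c	6-99	46	145-184	(98)RRK
GhHsf20	Gorai.007G010900	B2a	23-116	47	163-203	(257)KRAR
GhHsf6	Gorai.003G160600	B2b	25-118	46	164-199	(262)KRVRR
GhHsf9	Gorai.004G208800	B2c	24-117	60	167-200	(263)KRVRR
GhHsf26	Gorai.008G244400	B2d	17-103	51	154-187	(248)KRLRK
GhHsf5	Gorai.003G091700	B3	21-114	36	150-177	(216)RKRKRKR
GhHsf30	Gorai.010G020700	B4a	18-104	74	178-212	(276)KKR	(305)IGLNLM
GhHsf29	Gorai.009G213100	B4b	21-114	74	185-220	(325)KKR	(351)LRLNLM
GhHsf16	Gorai.006G125000	B4c	17-110	38	148-182	(160)RLRRK
GhHsf14	Gorai.005G102000	B4d	21-114	67	181-212	(193)KLRRR	(333)LGLNLM
GhHsf2	Gorai.002G135200	B4e	21-114	57	171-204	(297)KKR	(324)LSCIYR
GhHsf33	Gorai.011G027400	B5a	20-125	43	168-200	(182)RREK
GhHsf15	Gorai.006G087100	B5b	22-123	16	139-180	(105)KHEKFKR
GhHsf31	Gorai.010G070900	C1a	9-102	15	117-157	(188)KKRR
GhHsf11	Gorai.004G280100	C1b	9-102	29	131-163	(198)KRR
GhHsf27	Gorai.009G024700	C1c	8-101	10	111-163	(194)KKRR
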