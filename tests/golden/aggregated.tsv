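mirna	gene	score	rank	n_sources	rank_source1	rank_source2	rank_source3
hsa-miR-10	GENE00001	0.02083333333	1	3	2	2	1
hsa-miR-7	GENE00001	0.04583333333	2	3	6	3	2
hsa-miR-6	GENE00008	0.07916666667	3	3	4	4	11
hsa-miR-9	GENE00009	0.0875	4	3	1	1	19
hsa-miR-5	GENE00003	0.25	5	3	31	12	17
hsa-miR-1	GENE00002	0.2875	6	3	36	7	26
hsa-miR-9	GENE00004	0.35	7	3	11	39	34
hsa-miR-7	GENE00005	0.3583333333	8	3	62	14	10
hsa-miR-6	GENE00004	0.3625	9	3	8	13	66
hsa-miR-5	GENE00005	0.3708333333	10	3	5	78	6
hsa-miR-7	GENE00008	0.3875	11	2	7	6	
hsa-miR-2	GENE00009	0.4	12	3	28	63	5
hsa-miR-10	GENE00009	0.4	13	2	3		13
hsa-miR-6	GENE00001	0.4041666667	14	3	20	36	41
hsa-miR-4	GENE00002	0.4083333333	15	3	41	5	52
hsa-miR-7	GENE00010	0.4083333333	16	2	10	8	
hsa-miR-2	GENE00003	0.4208333333	17	3	55	37	9
hsa-miR-2	GENE00001	0.4291666667	18	3	18	77	8
hsa-miR-9	GENE00005	0.4416666667	19	2	23		3
hsa-miR-1	GENE00009	0.45	20	3	65	18	25
hsa-miR-8	GENE00001	0.4541666667	21	2	19	10	
hsa-miR-9	GENE00003	0.4708333333	22	3	54	27	32
hsa-miR-7	GENE00003	0.475	23	2	12	22	
hsa-miR-10	GENE00008	0.4916666667	24	2	29	9	
hsa-miR-3	GENE00010	0.4916666667	25	2	13	25	
hsa-miR-3	GENE00004	0.5	26	3	42	64	14
hsa-miR-6	GENE00003	0.5041666667	27	3	22	62	37
hsa-miR-10	GENE00007	0.5083333333	28	3	64	34	24
hsa-miR-2	GENE00002	0.5125	29	3	74	28	21
hsa-miR-6	GENE00009	0.5208333333	30	3	69	20	36
hsa-miR-5	GENE00002	0.5291666667	31	3	16	50	61
hsa-miR-9	GENE00002	0.5375	32	2	38	11	
hsa-miR-8	GENE00004	0.5416666667	33	3	49	24	57
hsa-miR-6	GENE00002	0.55	34	3	43	69	20
hsa-miR-9	GENE00010	0.55	35	2	37	15	
hsa-miR-5	GENE00009	0.5625	36	3	25	54	56
hsa-miR-1	GENE00003	0.5708333333	37	2	9		48
hsa-miR-8	GENE00008	0.575	38	3	27	33	78
hsa-miR-1	GENE00008	0.575	39	2		40	18
hsa-miR-6	GENE00007	0.575	40	2		43	15
hsa-miR-4	GENE00004	0.5875	41	2		16	45
hsa-miR-4	GENE00003	0.5958333333	42	3	15	70	58
hsa-miR-4	GENE00007	0.6	43	3	35	71	38
hsa-miR-3	GENE00007	0.6041666667	44	3	56	61	28
hsa-miR-4	GENE00006	0.6041666667	45	3	32	41	72
hsa-miR-9	GENE00001	0.6041666667	46	3	68	48	29
hsa-miR-4	GENE00001	0.6041666667	47	2		26	39
hsa-miR-9	GENE00007	0.6166666667	48	3	21	51	76
hsa-miR-4	GENE00008	0.6166666667	49	2		52	16
hsa-miR-6	GENE00006	0.6166666667	50	2		35	33
hsa-miR-1	GENE00007	0.6291666667	51	3	26	66	59
hsa-miR-8	GENE00009	0.6291666667	52	2		67	4
hsa-miR-3	GENE00006	0.6333333333	53	3	75	65	12
hsa-miR-10	GENE00004	0.6416666667	54	3	77	30	47
hsa-miR-2	GENE00005	0.6416666667	55	3	72	38	44
hsa-miR-4	GENE00005	0.6458333333	56	3	45	47	63
hsa-miR-5	GENE00006	0.6458333333	57	2	17	58	
hsa-miR-8	GENE00003	0.6458333333	58	2	52		23
hsa-miR-2	GENE00010	0.65	59	3	30	73	53
hsa-miR-5	GENE00008	0.6541666667	60	3	34	80	43
hsa-miR-3	GENE00001	0.6541666667	61	2	46		31
hsa-miR-9	GENE00006	0.6583333333	62	3	39	55	64
hsa-miR-6	GENE00010	0.6666666667	63	2	59	21	
hsa-miR-3	GENE00003	0.6708333333	64	2	58	23	
hsa-miR-8	GENE00006	0.675	65	2	53	29	
hsa-miR-1	GENE00005	0.6833333333	66	3	60	74	30
hsa-miR-1	GENE00001	0.6833333333	67	2	67	17	
hsa-miR-10	GENE00005	0.6958333333	68	1			7
hsa-miR-1	GENE00006	0.7041666667	69	2		19	70
hsa-miR-6	GENE00005	0.7166666667	70	2	61	31	
hsa-miR-5	GENE00004	0.7208333333	71	2		42	51
hsa-miR-8	GENE00010	0.7208333333	72	2	47		46
hsa-miR-5	GENE00007	0.7208333333	73	3	70	76	27
hsa-miR-7	GENE00002	0.725	74	1	14		
hsa-miR-7	GENE00004	0.7375	75	2		57	40
hsa-miR-7	GENE00006	0.7416666667	76	2	24		74
hsa-miR-10	GENE00006	0.7458333333	77	3	50	49	80
hsa-miR-5	GENE00010	0.7583333333	78	1			22
hsa-miR-10	GENE00003	0.7708333333	79	2		32	73
hsa-miR-10	GENE00010	0.7791666667	80	2	63	44	
hsa-miR-9	GENE00008	0.7833333333	81	3	51	75	62
hsa-miR-4	GENE00009	0.7833333333	82	2	33		75
hsa-miR-8	GENE00002	0.7833333333	83	2		53	55
hsa-miR-3	GENE00009	0.7875	84	2		59	50
hsa-miR-2	GENE00008	0.8041666667	85	2	71		42
hsa-miR-7	GENE00009	0.8041666667	86	2	44		69
hsa-miR-4	GENE00010	0.8125	87	1			35
hsa-miR-1	GENE00010	0.8291666667	88	2	40		79
hsa-miR-2	GENE00007	0.8333333333	89	2	48	72	
hsa-miR-3	GENE00002	0.8458333333	90	3	80	46	77
hsa-miR-1	GENE00004	0.8541666667	91	2	57	68	
hsa-miR-8	GENE00007	0.8541666667	92	1		45	
hsa-miR-2	GENE00006	0.8583333333	93	3	78	60	68
hsa-miR-3	GENE00005	0.8625	94	2		56	71
hsa-miR-2	GENE00004	0.8708333333	95	1			49
hsa-miR-5	GENE00001	0.875	96	2	76		54
hsa-miR-3	GENE00008	0.8791666667	97	2	66		65
hsa-miR-10	GENE00002	0.8875	98	2	73		60
hsa-miR-7	GENE00007	0.9416666667	99	2	79		67
hsa-miR-8	GENE00005	0.9958333333	100	1		79	
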