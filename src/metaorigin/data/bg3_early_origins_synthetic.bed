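# synthetic stand-in early-origin positions (78 records, fly-like arms)
# columns: chrom start end name score strand
chr2L	2366578	2367578	ori_1	0	.
chr2L	2616578	2617578	ori_2	0	.
chr2L	4355537	4356537	ori_3	0	.
chr2L	4884549	4885549	ori_4	0	.
chr2L	7430064	7431064	ori_5	0	.
chr2L	7680064	7681064	ori_6	0	.
chr2L	8349046	8350046	ori_7	0	.
chr2L	9217645	9218645	ori_8	0	.
chr2L	10258185	10259185	ori_9	0	.
chr2L	10757543	10758543	ori_10	0	.
chr2L	11201854	11202854	ori_11	0	.
chr2L	11451854	11452854	ori_12	0	.
chr2L	14200427	14201427	ori_13	0	.
chr2L	17807566	17808566	ori_14	0	.
chr2L	18406964	18407964	ori_15	0	.
chr2R	5778309	5779309	ori_16	0	.
chr2R	11408316	11409316	ori_17	0	.
chr2R	11993160	11994160	ori_18	0	.
chr2R	12243160	12244160	ori_19	0	.
chr2R	12493160	12494160	ori_20	0	.
chr2R	12827012	12828012	ori_21	0	.
chr2R	13249518	13250518	ori_22	0	.
chr2R	14985576	14986576	ori_23	0	.
chr2R	17107277	17108277	ori_24	0	.
chr2R	17576365	17577365	ori_25	0	.
chr2R	21049512	21050512	ori_26	0	.
chr2R	21919160	21920160	ori_27	0	.
chr2R	23813349	23814349	ori_28	0	.
chr2R	24063349	24064349	ori_29	0	.
chr2R	24313349	24314349	ori_30	0	.
chr2R	24563349	24564349	ori_31	0	.
chr3L	1508981	1509981	ori_32	0	.
chr3L	1758981	1759981	ori_33	0	.
chr3L	2576488	2577488	ori_34	0	.
chr3L	2833300	2834300	ori_35	0	.
chr3L	3365857	3366857	ori_36	0	.
chr3L	4702807	4703807	ori_37	0	.
chr3L	6420083	6421083	ori_38	0	.
chr3L	6670083	6671083	ori_39	0	.
chr3L	6920083	6921083	ori_40	0	.
chr3L	7766765	7767765	ori_41	0	.
chr3L	8182496	8183496	ori_42	0	.
chr3L	9586209	9587209	ori_43	0	.
chr3L	15668371	15669371	ori_44	0	.
chr3L	17155570	17156570	ori_45	0	.
chr3L	21602328	21603328	ori_46	0	.
chr3L	22640520	22641520	ori_47	0	.
chr3R	5169340	5170340	ori_48	0	.
chr3R	9901401	9902401	ori_49	0	.
chr3R	10579333	10580333	ori_50	0	.
chr3R	12237011	12238011	ori_51	0	.
chr3R	13511529	13512529	ori_52	0	.
chr3R	13761529	13762529	ori_53	0	.
chr3R	14011529	14012529	ori_54	0	.
chr3R	14282855	14283855	ori_55	0	.
chr3R	14634029	14635029	ori_56	0	.
chr3R	14884029	14885029	ori_57	0	.
chr3R	16333056	16334056	ori_58	0	.
chr3R	17405047	17406047	ori_59	0	.
chr3R	20900031	20901031	ori_60	0	.
chr3R	21350965	21351965	ori_61	0	.
chr3R	21629953	21630953	ori_62	0	.
chr3R	22947748	22948748	ori_63	0	.
chr3R	26933005	26934005	ori_64	0	.
chrX	2008633	2009633	ori_65	0	.
chrX	2832677	2833677	ori_66	0	.
chrX	3208833	3209833	ori_67	0	.
chrX	3651398	3652398	ori_68	0	.
chrX	5036318	5037318	ori_69	0	.
chrX	5450606	5451606	ori_70	0	.
chrX	12364487	12365487	ori_71	0	.
chrX	13230542	13231542	ori_72	0	.
chrX	13971964	13972964	ori_73	0	.
chrX	14692934	14693934	ori_74	0	.
chrX	15941268	15942268	ori_75	0	.
chrX	16485906	16486906	ori_76	0	.
chrX	17790676	17791676	ori_77	0	.
chrX	20929435	20930435	ori_78	0	.
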