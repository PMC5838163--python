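chr2	490300	529700	SE_1	253.185	.
chr2	1470300	1509700	SE_2	235.961	.
chr1	1710300	1749700	SE_3	232.579	.
chr1	1810300	1849700	SE_4	221.987	.
chr1	870300	909700	SE_5	221.485	.
chr1	1490300	1529700	SE_6	215.862	.
chr1	1010300	1049700	SE_7	212.811	.
chr2	410300	449700	SE_8	196.374	.
chr1	210300	249700	SE_9	183.144	.
chr2	1270300	1309700	SE_10	166.304	.
chr2	1570300	1609700	SE_11	160.833	.
chr2	990300	1029700	SE_12	157.395	.
chr2	849105	850895	RE_13	3.7843	.
chr2	1789224	1790777	RE_14	3.7721	.
chr1	708960	711040	RE_15	3.7112	.
chr2	1408817	1411183	RE_16	3.6755	.
chr2	1188947	1191053	RE_17	3.6333	.
chr1	1449111	1450889	RE_18	3.479	.
chr1	1469209	1470791	RE_19	3.3925	.
chr1	88791	91210	RE_20	3.3024	.
chr1	1889143	1890858	RE_21	3.2741	.
chr2	1349158	1350843	RE_22	3.2474	.
chr2	28825	31176	RE_23	3.2399	.
chr1	368811	371189	RE_24	3.1925	.
chr1	1289207	1290794	RE_25	3.1685	.
chr1	1089247	1090754	RE_26	3.0731	.
chr1	1628948	1631053	RE_27	3.0656	.
chr1	1148809	1151191	RE_28	3.0549	.
chr1	309198	310803	RE_29	3.0283	.
chr1	749225	750776	RE_30	2.993	.
chr2	1369246	1370754	RE_31	2.9785	.
chr2	8929	11071	RE_32	2.9766	.
chr2	729250	730750	RE_33	2.9046	.
chr1	48783	51217	RE_34	2.8547	.
chr2	368818	371182	RE_35	2.8498	.
chr1	1129187	1130813	RE_36	2.8364	.
chr1	1689018	1690982	RE_37	2.8114	.
chr1	1588988	1591013	RE_38	2.7898	.
chr1	328790	331210	RE_39	2.7846	.
chr1	68789	71211	RE_40	2.7683	.
chr1	488774	491226	RE_41	2.7597	.
chr2	1949171	1950830	RE_42	2.7483	.
chr2	649096	650905	RE_43	2.7366	.
chr2	249139	250861	RE_44	2.7081	.
chr2	48751	51249	RE_45	2.6912	.
chr1	1669096	1670904	RE_46	2.6795	.
chr1	29118	30882	RE_47	2.6505	.
chr2	1888983	1891018	RE_48	2.6186	.
chr1	8786	11214	RE_49	2.6145	.
chr1	1328911	1331089	RE_50	2.5959	.
chr2	788888	791113	RE_51	2.5412	.
chr1	548915	551085	RE_52	2.5395	.
chr2	1688923	1691078	RE_53	2.4709	.
chr2	129098	130902	RE_54	2.4693	.
chr2	288922	291078	RE_55	2.4609	.
chr2	809244	810757	RE_56	2.435	.
chr2	108773	111227	RE_57	2.4208	.
chr1	648870	651130	RE_58	2.4032	.
chr2	348869	351132	RE_59	2.3991	.
chr2	389033	390967	RE_60	2.322	.
chr1	1168960	1171041	RE_61	2.1964	.
chr2	1248904	1251096	RE_62	2.1896	.
chr2	969095	970905	RE_63	2.1436	.
chr1	289046	290955	RE_64	2.0827	.
chr1	1409137	1410863	RE_65	2.0639	.
chr2	1228833	1231168	RE_66	2.019	.
chr1	1649017	1650984	RE_67	1.9254	.
chr2	868799	871202	RE_68	1.8898	.
chr1	628966	631034	RE_69	1.7799	.
chr2	169169	170832	RE_70	1.7584	.
chr2	1829215	1830785	RE_71	1.6609	.
chr2	1148795	1151205	RE_72	1.6303	.
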