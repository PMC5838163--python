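# se_id	chrom	start	end	n_bins	h_score	class	n_hub_bins
SE_1	chr2	490300	529700	8	0.000000	non-hierarchical	0
SE_2	chr2	1470300	1509700	8	0.000000	non-hierarchical	0
SE_3	chr1	1710300	1749700	8	2.645751	hierarchical	1
SE_4	chr1	1810300	1849700	8	2.645751	hierarchical	1
SE_5	chr1	870300	909700	8	2.645751	hierarchical	1
SE_6	chr1	1490300	1529700	8	2.645751	hierarchical	1
SE_7	chr1	1010300	1049700	8	0.000000	non-hierarchical	0
SE_8	chr2	410300	449700	8	0.000000	non-hierarchical	0
SE_9	chr1	210300	249700	8	0.000000	non-hierarchical	0
SE_10	chr2	1270300	1309700	8	2.645751	hierarchical	1
SE_11	chr2	1570300	1609700	8	0.000000	non-hierarchical	0
SE_12	chr2	990300	1029700	8	2.645751	hierarchical	1
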