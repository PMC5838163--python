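chr1	1748113	1749700	SE4_c5	47.5413	.
chr1	1848087	1849700	SE5_c6	39.671	.
chr1	907677	909700	SE1_c5	33.279	.
chr1	1527236	1529700	SE3_c6	45.0122	.
chr2	1307569	1309700	SE9_c4	29.0993	.
chr2	1027845	1029700	SE8_c4	28.9417	.
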