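gene	intron_1	intron_2	intron_3	intron_4	intron_5	intron_6	intron_7	intron_8	intron_9	intron_10	intron_11	intron_12	intron_13
PLE-1	3021	5403	2621	3739	3511	1153	3995	1068	668	687	4692	1230	281
PLE-B9(75)	3009	5440	2586	2265	1481	1806	2205	1069	679	688	4291	883	281
PLE-B9(70)	3007	5440	2584	2259	1477	1791	2179	1044	661	685	4282	883	281
PLE-C4	2998	5421	2555	2253	1458	1797	2209	1068	663	687	3855	889	281
PLE-G2	3013	2195	2628	3753	3522	1155	3998	1079	667	689	4713	1232	281
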