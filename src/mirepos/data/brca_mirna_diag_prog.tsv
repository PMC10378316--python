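mirna	fc_unpaired	fc_paired	tcga_mirna	logrank_p	hr	ci_low	ci_high	tcga_dataset
hsa-miR-100	0.316	0.295	hsa-miR-100	0.0195	0.766	0.613	0.9576	GA
hsa-miR-101	0.474	0.278	hsa-miR-101-1	0.0021	0.691	0.546	0.8741	HiSeq
NA	NA	NA	hsa-miR-101-2	0.0278	0.805	0.6626	0.9769	HiSeq
hsa-miR-193a-3p	2.070	2.244	hsa-miR-193a	0.0060	1.481	1.1219	1.9555	HiSeq
hsa-miR-204	0.241	0.148	hsa-miR-204	0.0233	0.819	0.6905	0.9725	HiSeq
hsa-miR-205	0.246	0.180	hsa-miR-205	0.0335	0.871	0.7667	0.9904	GA
hsa-miR-301b	2.118	1.948	hsa-miR-301b	0.0100	1.410	1.0837	1.8342	GA
hsa-miR-30a	0.406	0.324	hsa-miR-30a	0.0176	0.843	0.7324	0.9711	HiSeq
hsa-miR-30a*	0.351	0.250	NA	NA	NA	NA	NA	NA
hsa-miR-379	0.478	0.418	hsa-miR-379	0.0480	0.797	0.6369	0.9981	GA
hsa-miR-615-3p	1.8673	2.531	hsa-miR-615	0.0068	1.332	1.0804	1.6414	GA
hsa-miR-7	2.4657	3.994	hsa-miR-7-2	0.0393	1.464	1.0182	2.1057	GA
NA	NA	NA	hsa-miR-7-3	0.0106	1.543	1.1036	2.1582	GA
hsa-miR-720	4.2969	5.964	hsa-miR-720	0.0179	2.867	1.189	6.9117	HiSeq
hsa-miR-99a	0.2919	0.242	hsa-miR-99a	0.0128	0.744	0.5901	0.939	GA
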