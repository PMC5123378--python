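chrom	pos	ref	alt	low	intermediate	high	normal
1	119854088	G	A	0.03	0.69	1.00	NA
1	136484167	C	T	0.08	0.62	1.00	0.027
1	14608116	T	C	0.13	0.71	1.00	0.020
1	14661826	T	C	0.11	0.60	0.97	0.028
1	14673788	G	A	0.26	0.64	1.00	0.021
1	14928841	T	C	0.13	0.61	1.00	NA
1	15372856	A	G	0.24	0.69	1.00	0.023
1	15373562	C	A	0.09	0.68	1.00	0.029
1	15443887	T	C	0.10	0.86	1.00	NA
1	15443893	G	A	0.10	0.86	1.00	NA
1	15462255	C	G	0.16	0.56	1.00	NA
1	15906203	T	G	0.19	0.70	1.00	NA
1	16519642	G	A	0.08	0.61	1.00	NA
1	1824789	T	C	0.11	0.63	1.00	0.026
12	25398281	C	T	0.12	0.63	1.00	NA
12	75715330	C	A	0.13	0.60	1.00	NA
22	24891418	A	C	0.21	0.70	1.00	0.030
22	44083442	T	C	NA	0.78	1.00	NA
13	101289801	C	A	0.13	0.65	1.00	NA
20	61537337	G	T	0.13	0.65	1.00	NA
17	48557299	G	T	0.11	0.74	1.00	NA
5	45262378	G	T	0.08	0.50	1.00	NA
19	4476902	T	C	0.15	0.65	1.00	NA
21	10372199	G	T	NA	0.57	1.00	NA
5	64907465	C	A	0.10	0.57	1.00	NA
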