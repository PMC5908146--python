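chrom_id	total_len_um	short_len_um	long_len_um	arm_ratio	n_chromomeres	nt_total_mb	nt_short_mb	nt_long_mb	nt_arm_ratio	compaction_total	compaction_short	compaction_long	pachytene_rank	somatic_rank
1	39.00±5.47	15.67±3.08	23.33±2.54	1.49±0.13	36	43.27	16.93	26.34	1.56	1.11	1.08	1.13	1	1
2	27.13±1.51	10.47±1.07	16.67±0.61	1.59±0.14	28	35.94	13.71	22.23	1.62	1.32	1.31	1.33	3	3
3	33.67±1.36	17.53±1.58	16.13±1.45	0.92±0.15	29	36.41	19.59	16.83	0.86	1.08	1.12	1.04	2	2
4	26.47±2.15	4.87±0.25	21.60±2.23	4.44±0.57	20	35.50	9.86	25.64	2.60	1.34	2.03	1.19	4	4
5	22.13±2.19	7.80±0.61	14.33±1.70	1.84±0.15	18	29.96	12.51	17.45	1.40	1.35	1.60	1.22	6	8
6	22.93±1.26	11.20±0.75	11.73±0.53	1.05±0.03	20	31.25	15.44	15.80	1.02	1.36	1.38	1.35	5	5
7	21.67±1.94	7.73±1.02	13.93±1.20	1.80±0.21	18	29.70	12.08	17.62	1.46	1.37	1.56	1.26	8	10
8	22.13±2.13	9.00±1.21	13.13±1.64	1.46±0.27	18	28.44	12.95	15.49	1.20	1.29	1.44	1.18	7	7
9	19.00±1.45	5.00±0.32	14.00±1.19	2.80±0.16	17	23.01	2.90	20.12	6.94	1.21	0.58	1.44	11	11
10	17.27±1.86	4.53±0.42	12.73±1.53	2.81±0.25	17	23.21	8.20	15.01	1.83	1.34	1.81	1.18	12	12
11	20.07±3.46	8.27±1.60	11.80±2.30	1.43±0.27	18	29.02	12.26	16.76	1.37	1.45	1.48	1.42	10	9
12	21.20±0.62	8.33±0.96	12.87±1.28	1.54±0.36	18	27.53	11.93	15.60	1.31	1.30	1.43	1.21	9	6
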