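# Synthetic stand-in per-arm map columns (NOT transcriptions of the
# cited public resources, which print no per-arm values).
# Constructed once, seed 20180419: the linkage/repeat/gene columns have
# a nonzero intercept against nucleotide length; the somatic column is
# proportional with per-arm compaction spread around 0.09-0.18 um/Mb.
chrom_arm	linkage_cm	somatic_um	repeat_count	gene_count
1L	108.0	3.559	27472	3035
1S	78.3	2.099	17966	1951
2L	97.7	2.916	22949	2632
2S	52.9	1.765	14827	1858
3L	72.1	2.271	19125	1930
3S	95.1	2.578	20508	2287
4L	110.9	3.598	26049	2941
4S	52.9	1.338	11974	1331
5L	66.9	2.352	18643	2182
5S	66.6	1.727	13430	1472
6L	71.3	1.954	17882	1988
6S	76.8	2.173	17293	1856
7L	90.7	2.522	19450	2136
7S	60.1	1.668	13715	1584
8L	69.6	2.226	16835	1961
8S	72.0	1.510	15284	1680
9L	81.3	2.784	21376	2320
9S	22.7	0.521	5121	771
10L	68.7	2.110	16628	1922
10S	43.2	1.135	10042	1161
11L	79.6	2.118	17570	1996
11S	55.2	1.543	13622	1600
12L	93.3	2.241	16965	1867
12S	50.4	1.698	12716	1466
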