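chrom_arm	name	markers	genetic_cm	physical_mb	percent_pos	um_pos
1S	P0439B06	C50102,S1442,C53447S,C970	5.1	0.5	1.74±0.36	0.68
2S	P0575F10	S2901,E60571	6.9	1.2	4.38±1.15	1.19
3S	OSJNBa0030C11	C1279	11.1	2.1	6.76±1.72	2.28
4L	OSJNBa0070M12	E3142S	129.6	35.0	97.57±0.83	25.82
5S	P0016H04	S12936,S782,S2649	6.6	0.6	3.10±0.86	0.69
6S	TrsA	Tandem repeats			1.44±0.86	0.33
7L	P0496C02	C596	105.7	27.8	90.19±1.58	19.54
8S	OSJNBa12_15D	RG29	3.0		3.34±0.85	0.74
9S	45S rDNA	Ribosomal RNA gene			~18.99±1.62	3.61
10S	OSJNBb0004A06	R2309,G89B,S21126	4.1	1.9	7.01±0.71	1.21
11S	5S rDNA	Ribosomal RNA gene			39.74±4.91	7.87
12L	TrsA	Tandem repeats			97.52±1.80	20.67
pericent	B1109A06	E2071SA,R1547				
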