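linkage_group	snps	patterns	scaffolds	length_cm
1	96218	80	2750	67.2
2	108293	65	3572	60.6
3	126472	109	2983	81.8
4	291390	59	8808	42.6
5	339005	117	10026	83.9
6	308909	125	9281	99.0
7	108411	99	2921	77.3
8	112476	113	2868	102.7
9	75934	94	1666	96.0
10	139849	122	3264	89.4
11	77993	111	2006	86.8
12	223246	83	7243	72.2
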