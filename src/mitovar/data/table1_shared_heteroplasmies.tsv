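sample	alleles_3424	maf_3424	alleles_14804	maf_14804	alleles_16117	maf_16117	heteroplasmy_count
A25	G/A	0.0542	G/A	0.1495	C/T	0.0916	3
A5	G/A	0.0787	G/A	0.2037	C/T	0.0180	3
A58	G/A	0.0311	G/A	0.2303	C/T	0.0490	3
A61			G/A	0.0566	C/T	0.0332	2
A66	G/A	0.0423	G/A	0.0658	C/T	0.1262	5
B33	G/A	0.0135	G/A	0.1395	C/T	0.0371	3
B4	G/A	0.0217	G/A	0.2483	C/T	0.0565	3
B45			G/A	0.1536	C/T	0.0735	3
B5	G/A	0.0344	G/A	0.3147	C/T	0.0315	3
B6	G/A	0.0243	G/A	0.2854	C/T	0.0783	3
B9	G/A	0.0197	G/A	0.1047	C/T	0.0334	3
C2	G/A	0.0508	G/A	0.0251	C/T	0.0213	4
C3	G/A	0.0139	G/A	0.0545	C/T	0.0431	7
C31	G/A	0.0246	G/A	0.0290	C/T	0.0399	7
C74	G/A	0.0240	G/A	0.0359	C/T	0.0404	3
D16			G/A	0.1282	C/T	0.0243	3
D25	G/A	0.0959	G/A	0.0984	C/T	0.0346	3
D29	G/A	0.0271	G/A	0.1319	C/T	0.0241	4
D54	G/A	0.0169	G/A	0.0993	C/T	0.0166	4
D58	G/A	0.0264	G/A	0.1678	C/T	0.0258	5
D62	G/A	0.0573	G/A	0.1297	C/T	0.0344	6
D63	G/A	0.0319	G/A	0.1403	C/T	0.0445	5
Z1			G/A	0.0232	C/T	0.0296	6
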