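index	r_bohr	e0_hartree	e1_hartree	e2_hartree
0	1.000000	-1.078969769198	0.190222024353	1.168500390434
1	1.140000	-1.117446624293	0.030381977836	0.878610217635
2	1.280000	-1.134110555272	-0.089930668968	0.645281396649
3	1.420000	-1.137080302980	-0.180764266775	0.456516061588
4	1.560000	-1.131490977613	-0.249457705071	0.302778134409
5	1.700000	-1.120628794835	-0.301463440205	0.176497948351
6	1.840000	-1.106609974162	-0.340793863392	0.071858833839
7	1.980000	-1.090833147877	-0.370363512940	-0.015444786251
8	2.120000	-1.074271745281	-0.392290031376	-0.088531205500
9	2.260000	-1.057642471470	-0.408142218404	-0.149673311172
10	2.400000	-1.041489338408	-0.419121245838	-0.200588718329
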