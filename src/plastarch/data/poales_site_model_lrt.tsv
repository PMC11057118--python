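gene	comparison	lnL_null	lnL_alt	np_null	np_alt	two_delta_L	df	p_printed	consistent
atpA	M0vsM3	-16937	-16174	211	215	1525.054	4	0	1
atpA	M1vsM2	-16320	-16301	212	214	37.6083	2	6.81E-09	1
atpA	M7vsM8	-16191	-16154	212	214	73.2202	2	1.11E-16	0
psbK	M0vsM3	-2042.2	-1953.3	211	215	177.742	4	0	1
psbK	M1vsM2	-1969.1	-1962.1	212	214	13.9514	2	0.0009343	1
psbK	M7vsM8	-1963.8	-1952.3	212	214	23.1282	2	9.50E-06	1
rbcL	M0vsM3	-8470.6	-8005.3	211	215	930.656	4	0	1
rbcL	M1vsM2	-8092.5	-8078.6	212	214	27.7414	2	9.46E-07	1
rbcL	M7vsM8	-8017.7	-7997.7	212	214	40.1185	2	1.94E-09	1
rpl22	M0vsM3	-516.87	-487.16	211	215	59.4117	4	3.86E-12	1
rpl22	M1vsM2	-496.97	-491.09	212	214	11.7556	2	0.0028009	1
rpl22	M7vsM8	-496.55	-487.74	212	214	17.6208	2	0.0001492	1
rpoB	M0vsM3	-6799.1	-6579.9	211	215	438.402	4	0	1
rpoB	M1vsM2	-6641.3	-6631.8	212	214	18.9368	2	7.73E-05	1
rpoB	M7vsM8	-6585.8	-6573	212	214	25.6444	2	2.70E-06	1
rps2	M0vsM3	-3175.9	-3110.4	211	215	130.973	4	0	1
rps2	M1vsM2	-3130.3	-3124.7	212	214	11.2962	2	0.0035241	1
rps2	M7vsM8	-3118.9	-3108.1	212	214	21.5384	2	2.10E-05	1
rps7	M0vsM3	-837.15	-803.96	211	215	66.3752	4	1.32E-13	1
rps7	M1vsM2	-808.53	-804.83	212	214	7.40333	2	0.0246824	1
rps7	M7vsM8	-812.13	-806.16	212	214	11.9333	2	0.0025629	1
ycf3	M0vsM3	-1398.6	-1312.8	211	215	171.615	4	0	1
ycf3	M1vsM2	-1316.9	-1313.9	212	214	6.02576	2	0.04915	1
ycf3	M7vsM8	-1321.7	-1315.1	212	214	13.189	2	0.0013679	1
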