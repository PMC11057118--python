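name	kind	length	region	introns	trans
psbA	CDS	1062	LSC	-	0
trnH-GUG	tRNA	75	LSC	-	0
trnK-UUU	tRNA	74	LSC	-	0
matK	CDS	1530	LSC	-	0
rps16	CDS	261	LSC	860	0
trnQ-UUG	tRNA	72	LSC	-	0
psbK	CDS	186	LSC	-	0
psbI	CDS	111	LSC	-	0
trnS-GCU	tRNA	88	LSC	-	0
trnG-UCC	tRNA	72	LSC	-	0
trnR-UCU	tRNA	72	LSC	-	0
atpA	CDS	1524	LSC	-	0
atpF	CDS	555	LSC	700	0
atpH	CDS	246	LSC	-	0
atpI	CDS	744	LSC	-	0
rps2	CDS	711	LSC	-	0
rpoC2	CDS	4140	LSC	-	0
rpoC1	CDS	2052	LSC	740	0
rpoB	CDS	3213	LSC	-	0
trnC-GCA	tRNA	72	LSC	-	0
petN	CDS	90	LSC	-	0
psbM	CDS	105	LSC	-	0
trnD-GUC	tRNA	74	LSC	-	0
trnY-GUA	tRNA	84	LSC	-	0
trnE-UUC	tRNA	73	LSC	-	0
trnT-GGU	tRNA	72	LSC	-	0
psbD	CDS	1062	LSC	-	0
psbC	CDS	1386	LSC	-	0
trnS-UGA	tRNA	87	LSC	-	0
psbZ	CDS	189	LSC	-	0
trnG-GCC	tRNA	72	LSC	-	0
trnfM-CAU	tRNA	74	LSC	-	0
rps14	CDS	303	LSC	-	0
psaB	CDS	2205	LSC	-	0
psaA	CDS	2253	LSC	-	0
ycf3	CDS	507	LSC	720,740	0
trnS-GGA	tRNA	87	LSC	-	0
rps4	CDS	606	LSC	-	0
trnT-UGU	tRNA	73	LSC	-	0
trnL-UAA	tRNA	85	LSC	-	0
trnF-GAA	tRNA	73	LSC	-	0
ndhJ	CDS	477	LSC	-	0
ndhK	CDS	678	LSC	-	0
ndhC	CDS	363	LSC	-	0
trnV-UAC	tRNA	74	LSC	-	0
trnM-CAU	tRNA	73	LSC	-	0
atpE	CDS	402	LSC	-	0
atpB	CDS	1497	LSC	-	0
rbcL	CDS	1428	LSC	-	0
accD	CDS	1464	LSC	-	0
psaI	CDS	111	LSC	-	0
ycf4	CDS	555	LSC	-	0
cemA	CDS	690	LSC	-	0
petA	CDS	963	LSC	-	0
psbJ	CDS	123	LSC	-	0
psbL	CDS	117	LSC	-	0
psbF	CDS	120	LSC	-	0
psbE	CDS	252	LSC	-	0
petL	CDS	96	LSC	-	0
petG	CDS	114	LSC	-	0
trnW-CCA	tRNA	74	LSC	-	0
trnP-UGG	tRNA	74	LSC	-	0
psaJ	CDS	135	LSC	-	0
rpl33	CDS	201	LSC	-	0
rps18	CDS	306	LSC	-	0
rpl20	CDS	354	LSC	-	0
clpP	CDS	591	LSC	800,620	0
psbB	CDS	1527	LSC	-	0
psbT	CDS	108	LSC	-	0
psbN	CDS	132	LSC	-	0
psbH	CDS	222	LSC	-	0
petB	CDS	648	LSC	750	0
petD	CDS	483	LSC	720	0
rpoA	CDS	1014	LSC	-	0
rps11	CDS	417	LSC	-	0
rpl36	CDS	114	LSC	-	0
infA	CDS	234	LSC	-	0
rps8	CDS	405	LSC	-	0
rpl14	CDS	369	LSC	-	0
rpl16	CDS	408	LSC	1020	0
rps3	CDS	657	LSC	-	0
rpl22	CDS	429	LSC	-	0
rpl2	CDS	822	IR	660	0
rpl23	CDS	282	IR	-	0
trnI-CAU	tRNA	74	IR	-	0
ycf2	CDS	6837	IR	-	0
ycf15	CDS	171	IR	-	0
trnL-CAA	tRNA	81	IR	-	0
ndhB	CDS	1533	IR	680	0
rps7	CDS	468	IR	-	0
rps12	CDS	372	IR	-	1
trnV-GAC	tRNA	72	IR	-	0
rrn16	rRNA	1491	IR	-	0
trnI-GAU	tRNA	72	IR	940	0
trnA-UGC	tRNA	73	IR	800	0
rrn23	rRNA	2810	IR	-	0
rrn4.5	rRNA	103	IR	-	0
rrn5	rRNA	121	IR	-	0
trnR-ACG	tRNA	74	IR	-	0
trnN-GUU	tRNA	72	IR	-	0
ndhF	CDS	2220	SSC	-	0
rpl32	CDS	174	SSC	-	0
trnL-UAG	tRNA	80	SSC	-	0
ccsA	CDS	966	SSC	-	0
ndhD	CDS	1503	SSC	-	0
psaC	CDS	246	SSC	-	0
ndhE	CDS	306	SSC	-	0
ndhG	CDS	531	SSC	-	0
ndhI	CDS	543	SSC	-	0
ndhA	CDS	1092	SSC	1080	0
ndhH	CDS	1182	SSC	-	0
rps15	CDS	273	SSC	-	0
ycf1	CDS	5301	SSC	-	0
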