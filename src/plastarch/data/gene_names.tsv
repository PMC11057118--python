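variant	canonical
16s ribosomal rna	rrn16
16s rrna	rrn16
rrn16s	rrn16
23s ribosomal rna	rrn23
23s rrna	rrn23
rrn23s	rrn23
4.5s ribosomal rna	rrn4.5
4.5s rrna	rrn4.5
rrn4.5s	rrn4.5
5s ribosomal rna	rrn5
5s rrna	rrn5
rrn5s	rrn5
trnfm-cau	trnfM-CAU
trn-fmet	trnfM-CAU
ycf1a	ycf1
ycf1b	ycf1
pafi	ycf3
pafii	ycf4
pbf1	psbN
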