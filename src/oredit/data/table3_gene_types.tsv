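organelle	sample	gene	type	occurrence
chloroplast	CD	psbC	C/T	3
chloroplast	CD	psbC	A/G	5
chloroplast	CD	ndhB-2	C/T	36
chloroplast	CDT	rpoC2	A/G	4
chloroplast	CDT	ndhB	G/A	7
chloroplast	WD	ndhB-2	C/T	5
chloroplast	WDT	EPlORYSAT000373811	C/T	3
mitochondria	CD	nad3	C/T	21
mitochondria	CD	rps12	C/T	8
mitochondria	CD	rsp2	G/A	7
mitochondria	CD	nad4	C/T	9
mitochondria	CD	cox2	C/T	21
mitochondria	CD	atp6	G/A	20
mitochondria	CD	nad5	G/A	13
mitochondria	CD	rps4	G/A	5
mitochondria	CD	rps19	C/T	8
mitochondria	CD	nad4L	C/T	11
mitochondria	CD	cob	G/A	5
mitochondria	CD	nad1	G/A	10
mitochondria	CD	mat-r	G/A	12
mitochondria	CD	rps1	G/A	8
mitochondria	CD	ccmFn	G/A	22
mitochondria	CD	ccmFc	C/T	21
mitochondria	CD	nad9	C/T	6
mitochondria	CD	nad2	C/T	9
mitochondria	CD	nad2	G/A	6
mitochondria	CD	ccmB	C/T	28
mitochondria	CDT	rps3	C/T	9
mitochondria	CDT	pseudo-rpl16	C/T	3
mitochondria	CDT	nad3	C/T	14
mitochondria	CDT	rps12	C/T	10
mitochondria	CDT	rps2	G/A	10
mitochondria	CDT	nad4	C/T	7
mitochondria	CDT	cox2	C/T	20
mitochondria	CDT	apt6	G/A	22
mitochondria	CDT	nad5	G/A	6
mitochondria	CDT	nad1	G/A	17
mitochondria	CDT	rps4	G/A	10
mitochondria	CDT	atp9	C/T	5
mitochondria	CDT	rps19	C/T	4
mitochondria	CDT	nad4L	C/T	4
mitochondria	CDT	cob	G/A	6
mitochondria	CDT	mat-r	G/A	6
mitochondria	CDT	rps1	G/A	5
mitochondria	CDT	ccmFn	G/A	6
mitochondria	CDT	ccmFc	C/T	16
mitochondria	CDT	apt1	C/T	5
mitochondria	CDT	nad9	C/T	6
mitochondria	CDT	nad2	C/T	12
mitochondria	CDT	ccmB	C/T	11
mitochondria	WD	rps3	C/T	10
mitochondria	WD	nad3	C/T	11
mitochondria	WD	rsp12	C/T	4
mitochondria	WD	nad4	C/T	6
mitochondria	WD	cox2	C/T	21
mitochondria	WD	atp6	G/A	12
mitochondria	WD	nad5	G/A	12
mitochondria	WD	rps4	G/A	6
mitochondria	WD	atp9	C/T	4
mitochondria	WD	rps19	C/T	3
mitochondria	WD	nad4L	C/T	11
mitochondria	WD	cob	G/A	10
mitochondria	WD	nad1	G/A	9
mitochondria	WD	mat-r	G/A	6
mitochondria	WD	ccmFn	G/A	12
mitochondria	WD	ccmFc	C/T	15
mitochondria	WD	atp1	C/T	4
mitochondria	WD	nad9	C/T	6
mitochondria	WD	nad2	C/T	10
mitochondria	WD	nad2	G/A	2
mitochondria	WDT	rps3	C/T	15
mitochondria	WDT	pseudo-rpl16	C/T	10
mitochondria	WDT	nad3	C/T	15
mitochondria	WDT	rps12	C/T	5
mitochondria	WDT	rps2	G/A	13
mitochondria	WDT	nad4	C/T	12
mitochondria	WDT	cox2	C/T	19
mitochondria	WDT	atp6	G/A	18
mitochondria	WDT	nad5	G/A	15
mitochondria	WDT	nad1	G/A	18
mitochondria	WDT	rps13	G/A	7
mitochondria	WDT	rps4	G/A	11
mitochondria	WDT	cob	G/A	11
mitochondria	WDT	mat-r	G/A	7
mitochondria	WDT	ccmFn	G/A	16
mitochondria	WDT	ccmFc	C/T	11
mitochondria	WDT	cox1	C/T	9
mitochondria	WDT	nad9	C/T	13
mitochondria	WDT	nad2	C/T	19
mitochondria	WDT	nad2	G/A	12
mitochondria	WDT	ccmB	C/T	10
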