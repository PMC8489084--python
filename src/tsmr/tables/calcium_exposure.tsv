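rsid	chrom	gene	effect_allele	other_allele	eaf	beta	se	pvalue
rs1801725	3	CASR	T	G	0.15	0.071	0.004	8.90E-86
rs1570669	20	CYP24A1	G	A	0.34	0.018	0.003	9.10E-12
rs1550532	2	DGKD	C	G	0.31	0.018	0.003	8.20E-11
rs7481584	11	CARS	G	A	0.70	0.018	0.003	1.20E-10
rs780094	2	GCKR	T	C	0.42	0.017	0.003	1.30E-10
rs7336933	13	DGKH	G	A	0.85	0.022	0.004	9.10E-10
rs10491003	10	GATA3	T	C	0.09	0.027	0.005	4.80E-09
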