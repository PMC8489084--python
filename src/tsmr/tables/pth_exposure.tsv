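rsid	chrom	gene	effect_allele	other_allele	eaf	beta	se	pvalue
rs6127099	20	CYP24A1	T	A	0.34	0.070	0.003	2.40E-72
rs4074995	5	RGS14	G	A	0.71	0.030	0.003	3.30E-23
rs219779	21	CLDN14	G	A	0.75	0.040	0.003	8.90E-22
rs4443100	22	RTDR1	G	C	0.32	0.020	0.003	4.10E-11
rs73186030	3	CASR	T	C	0.14	0.030	0.004	1.20E-09
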