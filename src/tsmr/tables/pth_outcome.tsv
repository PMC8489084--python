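rsid	chrom	gene	effect_allele	other_allele	eaf	beta	se	pvalue
rs6127099	20	CYP24A1	T	A	NA	0.021	0.030	0.494
rs4074995	5	RGS14	G	A	NA	0.029	0.030	0.337
rs219779	21	CLDN14	G	A	NA	-0.017	0.030	0.582
rs4443100	22	RTDR1	G	C	NA	-0.025	0.029	0.390
rs73186030	3	CASR	T	C	NA	0.051	0.039	0.198
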