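rsid	chrom	gene	effect_allele	other_allele	eaf	beta	se	pvalue
rs3755967	4	GC	C	T	NA	0.032	0.029	0.274
rs12785878	11	DHCR7	T	G	NA	-0.055	0.033	0.090
rs10741657	11	CYP2R1	A	G	NA	-0.001	0.027	0.972
rs17216707	20	CYP24A1	T	C	NA	-0.033	0.035	0.344
rs10745742	12	AMDHD1	T	C	NA	-0.019	0.028	0.495
rs8018720	14	SEC23A	G	C	NA	0.019	0.034	0.586
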