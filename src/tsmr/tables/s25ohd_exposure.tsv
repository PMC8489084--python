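rsid	chrom	gene	effect_allele	other_allele	eaf	beta	se	pvalue
rs3755967	4	GC	C	T	0.72	0.089	0.002	4.74E-343
rs12785878	11	DHCR7	T	G	0.75	0.036	0.002	3.80E-62
rs10741657	11	CYP2R1	A	G	0.40	0.031	0.002	2.05E-46
rs17216707	20	CYP24A1	T	C	0.79	0.026	0.003	8.14E-23
rs10745742	12	AMDHD1	T	C	0.40	0.017	0.002	1.88E-14
rs8018720	14	SEC23A	G	C	0.18	0.017	0.003	4.72E-09
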