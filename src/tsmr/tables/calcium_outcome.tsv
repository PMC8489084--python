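rsid	chrom	gene	effect_allele	other_allele	eaf	beta	se	pvalue
rs1801725	3	CASR	T	G	NA	0.052	0.039	0.186
rs1570669	20	CYP24A1	G	A	NA	-0.001	0.028	0.981
rs1550532	2	DGKD	C	G	NA	-0.017	0.028	0.545
rs7481584	11	CARS	G	A	NA	-0.004	0.030	0.904
rs780094	2	GCKR	T	C	NA	0.085	0.028	0.002
rs7336933	13	DGKH	G	A	NA	-0.021	0.037	0.568
rs10491003	10	GATA3	T	C	NA	-0.013	0.046	0.784
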