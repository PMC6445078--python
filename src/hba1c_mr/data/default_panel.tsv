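# Default 17-SNP HbA1c instrument panel.
# SYNTHETIC PLACEHOLDER VALUES: per-allele weights (percent HbA1c units) and
# risk-allele frequencies below are plausible placeholders, NOT literature values.
# Edit this file (or supply your own in the same dialect) to use published weights.
# Eligibility flags encode: reported pleiotropy with non-glycemic traits, a
# Hardy-Weinberg screen at P < 1e-4, in-sample association with HbA1c, and
# identification in East Asian populations.
# The G6PC2/ABCB11 locus is genotyped under two interchangeable rsids
# (rs552976 / rs3755157); one entry is kept and it carries the HWE-failure and
# non-significance flags of that locus. Membership is fully configurable here.
rsid	locus	risk_allele	weight	freq	pleiotropy_reported	hwe_pass	assoc_significant	east_asian_identified	note
rs7072268	HK1	T	0.032	0.45	0	1	0	0
rs1402837	G6PC2	T	0.041	0.25	0	1	1	0
rs13266634	SLC30A8	C	0.035	0.55	1	0	1	1
rs855791	TMPRSS6	A	0.052	0.40	1	1	1	1
rs1046896	FN3K	T	0.028	0.30	0	1	1	1
rs4737009	ANK1	A	0.024	0.20	0	1	1	1
rs552976	G6PC2/ABCB11	G	0.038	0.35	0	0	0	1	alias rs3755157
rs11667918	MYO9B	T	0.022	0.30	0	0	1	1
rs6684514	TMEM79	G	0.030	0.50	1	1	1	1
rs9399137	HBS1L/MYB	C	0.048	0.25	1	1	1	1
rs9933309	CYBA	C	0.044	0.35	0	1	1	1
rs1799884	GCK	T	0.045	0.20	1	1	1	1
rs6474359	ANK1	T	0.019	0.10	0	1	0	1
rs2779116	SPTA1	T	0.026	0.30	0	1	1	1
rs1387153	MTNR1B	T	0.033	0.45	1	1	0	1
rs7903146	TCF7L2	T	0.029	0.15	1	1	1	1
rs7772603	CDKAL1	C	0.021	0.40	1	1	1	1
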