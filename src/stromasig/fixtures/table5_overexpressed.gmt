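table5_over_both	literature genes overexpressed in gastric cancer, detected by both dissection methods at P<0.05	APOE	AURKA	CCNE1	CDC20	CDC25B	CXCR4	E2F1	EGR1	GRB2	HK2	ICAM1	INHBA	LOXL2	MCM3	PTMA	SPARC
table5_over_lcm_only	literature genes overexpressed in gastric cancer, detected only in LCM data	EGFR	HGF	MET	RHOA	TNS4
table5_over_macro_only	literature genes overexpressed in gastric cancer, detected only in macrodissection data	AKT1	ANXA2	CALR	CCNB1	EEF2	ESM1	HIF1A	MINA	PHB
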