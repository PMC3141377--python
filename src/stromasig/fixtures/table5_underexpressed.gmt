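table5_under_both	literature genes underexpressed in gastric cancer, detected by both dissection methods at P<0.05	ANXA10	CASP6	CASP7	CDH1	CTNNA1	GSN	HLA-F	IQGAP2	KCNE2	KLF4	MUC6	RARB	SMAD4
table5_under_lcm_only	literature genes underexpressed in gastric cancer, detected only in LCM data	ANXA7	BAD	HLA-B	HLA-E	HLA-G	PRSS8	PTEN	SDHB	SH3GLB1	TFF1
table5_under_macro_only	literature genes underexpressed in gastric cancer, detected only in macrodissection data	CDKN2B	FHIT
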