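method	gene	fold_change
micro	HPGD	-25.0
micro	HRASLS2	-20.0
micro	ABCC3	-20.0
micro	SLC25A37	-16.7
micro	ABHD2	-14.3
micro	VIPR1	-10.0
micro	CYTIP	-9.1
micro	GALNT6	-9.1
micro	SULT1A2	-9.1
micro	OAS1	-8.3
micro	PDCD4	-7.1
micro	NR3C2	-7.1
micro	DOCK6	-6.3
micro	SULT1A1	-5.9
micro	ZFYVE26	-5.9
micro	213212_x_at	-5.6
micro	DSCR3	-5.3
micro	TMEM131	-5.3
micro	ECHDC2	-5.0
micro	DENND1B	-5.0
micro	KIAA0141	-4.8
micro	RNF103	-4.8
micro	PDCD4	-4.5
micro	CABIN1	-4.5
micro	222371_at	-4.3
micro	RRBP1	-4.0
micro	CC2D1A	-3.8
micro	216438_s_at	-3.8
micro	SGSM3	-3.8
micro	ARPC2	-3.7
micro	TRAK1	-3.6
micro	GNA11	-3.6
micro	PAFAH1B1	-3.4
micro	CNDP2	-3.2
micro	SPOP	-3.1
micro	PARP4	-3.1
micro	ERLIN1	-2.9
macro	208498_s_at	-11.1
macro	SIDT2	-7.7
macro	MUC5AC	-5.9
macro	CTAGE5	-5.0
macro	GNA11	-3.8
macro	ARFIP1	-3.4
macro	214316_x_at	-3.3
macro	222149_x_at	-3.3
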