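gene	fold_change
BMP3	38.5
BGN	30.3
TRIO	18.5
GADD45GIP1	17.2
MIER2	16.7
KIFC3	16.4
217318_x_at	13.7
217219_at	13.2
RUNX2	12.5
SMARCD1	12.0
KIRREL	12.0
215621_s_at	12.0
GRM2	10.0
FJX1	10.0
AIF1	10.0
THY1	9.1
CARD10	9.1
SIM2	9.1
AIF1	9.1
APOBEC3G	8.3
RHAG	8.3
HIST1H4C	6.3
LEPRE1	5.9
ETNK2	5.6
TRIP6	5.3
FAM125B	5.3
NPR1	5.3
DSCC1	5.3
CLUL1	5.0
HMGB3	4.5
E2F3	4.3
AIMP2	4.2
ATAD5	4.0
E2F1	3.8
FKSG49	3.7
DVL2	3.7
TIPRL	2.9
EIF2C3	2.9
NAT10	2.8
MED27	2.7
PIN4	2.7
CTPS	2.6
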