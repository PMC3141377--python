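gene	fold_change
LY6E	24.4
IL8	22.7
CA12	20.0
SBNO2	19.2
UBE2S	17.2
CYR61	17.2
ANGPT2	15.9
COL6A2	14.3
BOP1	13.2
COL1A1	13.2
LPL	13.0
MFGE8	12.8
APOE	12.2
G6PC3	10.9
215900_at	10.3
NUP62	10.0
MRPL4	10.0
GNL3L	10.0
MCAM	9.1
PDLIM7	9.1
216472_at	9.1
ACTN1	9.1
BYSL	9.1
GNAI2	8.3
NCAPH2	8.3
CD14	8.3
EXOSC4	8.3
OBFC2B	8.3
PPP1R15A	7.7
COL1A2	7.7
GPX1	7.7
MIF	7.7
NME1	7.1
PPIL2	7.1
CCDC85B	7.1
SPARC	6.7
C8orf55	6.7
SRM	6.7
NGLY1	6.7
RHOB	6.3
ACTN1	5.9
LOXL2	5.9
COL5A2	5.9
TRIM28	5.6
218982_s_at	5.6
C7orf44	5.3
UBE2C	5.3
CEP76	5.3
BIRC5	5.3
PNO1	5.0
FSTL1	5.0
GRINA	4.8
MRTO4	4.8
STC1	4.8
MRPL12	4.5
FKBP1A	4.5
IFI30	4.5
KPNA6	4.3
216532_x_at	4.3
CENPI	4.2
PPM1G	4.2
ICT1	3.7
SFRS14	3.6
CTPS	3.6
IMP4	3.3
UBE2G2	3.2
ISG20L2	3.2
EIF4A1	3.1
HDGF	2.6
PSMD14	2.6
220856_x_at	2.4
CNOT3	2.4
GLT25D1	2.0
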