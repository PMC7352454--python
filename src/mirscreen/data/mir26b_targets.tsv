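gene	transcript_id	ratio_fc_DG75	ratio_fc_ST486	crispr_fc	crispr_p	sites_cds	sites_utr3
COPS2	ENST00000388901	5.1	4.0	-13.9	4.97e-86	7mA1	7mA1
EZH2	ENST00000320356	2.3	2.2	-9.4	3.87e-45	7mA1	8m
KPNA2	ENST00000330459	2.5	3.3	-6.6	1.16e-6		8m
MRPL15	ENST00000260102	2.2	2.7	-6	5.03e-43	7mA1
NOL12	ENST00000359114	2.2	2.1	-5.6	2.67e-47	8m	7mA1
EIF4E	ENST00000505992	2.9	4.3	-4.3	5.76e-12
TRAPPC4	ENST00000533632	2.1	2.3	-3.7	1.0e-8		7mA1
ALG1	ENST00000262374	2.3	2.5	-3.2	0.042		7m8
FANCF	ENST00000327470	3.4	2.6	-2.4	3.52e-4		7mA1/8m
B3GNT2	ENST00000301998	3.1	2.9	-1.9	1	8m
MT2A	ENST00000245185	3.4	2.4	-1.7	0.045
NXT1	ENST00000254998	2.3	2.3	-1.5	1
MT1B	ENST00000334346	2.3	2.2	-1.4	1
MSMO1	ENST00000261507	2.3	2.5	-1.4	1		8m
PPP1CC	ENST00000335007	2.9	3.8	-1.2	1	7mA1
MT1E	ENST00000306061	2.2	2.7	-1.2	1
MPV17L2	ENST00000599612	2.6	2.5	-1.2	1	8m
RHOQ	ENST00000238738	2.8	2.5	-1.2	1		7mA1/7m8/8m
TBC1D7	ENST00000379300	2.0	2.8	-1.2	1	8m
TMEM156	ENST00000381938	3.0	2.8	-1.1	1	8m	7mA1
REEP4	ENST00000306306	4.6	4.1	-1.1	1		7m8
ASB10	ENST00000420175	2.1	3.4	-1.1	1
OSCP1	ENST00000235532	2.9	2.4	-1	1
H3F3C	ENST00000340398	2.3	3.0	-1	1
PRMT3	ENST00000331079	2.1	2.7	1	1	7mA1
ZDHHC6	ENST00000369405	4.2	3.9	1	1		8m
DIABLO	ENST00000650715	2.1	2.1	1.1	1		7mA1
TXNDC17	ENST00000250101	2.5	2.1	1.1	1	7mA1
MGST1	ENST00000396209	3.5	4.5	1.1	1
MSRB2	ENST00000376510	3.8	3.8	1.2	1		7mA1
FRAT2	ENST00000371019	3.7	3.3	1.2	1		8m
ADAM19	ENST00000257527	2.4	2.1	1.3	1		8m
PRKCD	ENST00000330452	4.2	3.1	1.3	1		8m
ACBD5	ENST00000396271	3.3	2.5	1.3	1		7mA1/8m
ZNF410	ENST00000555044	2.4	2.4	1.3	1		8m
ACYP2	ENST00000394666	2.4	2.6	1.4	1
BID	ENST00000317361	2.7	3.6	1.6	1		8m
SLC25A36	ENST00000324194	2.3	2.3	1.6	1
CRADD	ENST00000332896	2.0	2.4	1.6	1		8m
POLR3G	ENST00000369314	2.4	3.9	1.7	1
SAAL1	ENST00000524803	2.2	2.3	1.7	0.984	7mA1/8m
TMEM206	ENST00000261455	3.0	4.2	1.8	6.96e-4
LINC00847	ENST00000501855	2.8	2.9
LOC100294145	N/A	2.2	2.1
MT1L	ENST00000565768	2.8	2.3
XLOC_l2_008009	TCONS_l2_00014564	2.5	2.9
lnc-C2orf81-2	lnc-C2orf81-2:1-2	2.3	2.2				7m8/8m
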