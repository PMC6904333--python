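pairsig-signature	1
endpoint	OS
label	published-neuroblastoma-10-pair
units_note	rank-based; any non-negative abundance unit
cutoff	-4.774
cutoff_method	roc
n_pairs	10
gene1	gene2	coefficient
CDHR2	ACRV1	-0.250693546
SNCB	KCNB2	-0.410999623
BRINP1	TBX15	-0.168095779
KCNN1	BHLHE22	-0.384018203
EFNB3	EREG	-1.48200304
UNC13A	CNTNAP4	-0.429605222
IGFBPL1	SH3GL3	-0.424862085
IGFBPL1	TMEM88B	-0.878692179
OSR1	SPPL2C	0.002590887
CIB4	FXYD6-FXYD2	-0.595746694
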