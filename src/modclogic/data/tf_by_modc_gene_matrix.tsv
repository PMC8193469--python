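# synthetic reconstruction of the TF x moDC-gene binding-site matrix
# (the original is not available in machine-readable form); entries
# marked with * are previously reported interactions
tf	TLR8	TLR7	TLR6	TLR4	TLR3	NCOR2	LY75	CLEC4A	CD83	CD48	CD226	CD209	CD1C	CD1B	CD1A	THBD	ITGAX	CCL22	CCL2
AHR	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
AP1	0	0	0	1	0	0	1	0	0	0	0	1	0	0	0	0	0	0	0
BATF3	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0
CEBPA	0	0	0	1	0	0	0	0	0	1	0	0	1	1	1	1	0	0	1
CEBPB	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CREB	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0
EGR2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ELK4	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
FOS	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
FOXO1	0	0	1	1	0	0	1	1	0	1	0	0	0	0	0	0	0	0	1
IRF4	0	1	0	1	1	1	1	0	1	0	1	1	1	1	1*	0	1*	1	0
IRF8	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
KLF4	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
MAFB	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
NFKB	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
NR4A1	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0
PRDM1	0	0	0	0	0	0	0	0	0	0	0	0	1	1	1	0	0	0	0
PU1	0	0	0	0	0	0	0	0	0	1	0	0	1	1	1	0	1*	0	0
STAT3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
STAT5	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
STAT6	1*	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
USF1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
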