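# synthetic reconstruction of the TF x TF predicted-interaction matrix
# (the original is not available in machine-readable form); entries
# marked with * are previously reported interactions
tf	CEBPA	IRF4	IRF8	MAFB	PRDM1
AHR	0	1	0	1	1
PU1	1*	1	1	0	0
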