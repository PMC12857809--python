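Th1_illustrative	illustrative example set, not a curated signature	TBX21	IFNG	IL12RB2	CXCR3	STAT4
Th2_illustrative	illustrative example set, not a curated signature	GATA3	IL4	IL5	IL13	CCR4	PTGDR2
M2_macrophage_illustrative	illustrative example set, not a curated signature	MRC1	CD163	CCL13	CCL18	MSR1
eosinophil_illustrative	illustrative example set, not a curated signature	CCR3	SIGLEC8	IL5RA	PRG2	EPX
tuft_illustrative	illustrative example set, not a curated signature	POU2F3	TRPM5	AVIL	ALOX5	PTGS1
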