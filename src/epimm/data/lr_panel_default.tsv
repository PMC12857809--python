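# default epithelial-ligand / immune-receptor recruitment panel (ligand<TAB>receptor)
CCL26	CCR3
CCL20	CCR6
TSLP	IL7R
IL33	IL1RL1
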