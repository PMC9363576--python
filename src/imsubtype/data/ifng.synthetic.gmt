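IFNG_signature	synthetic surrogate Th1/IFN-gamma gene list	IFNG	STAT1	IDO1	CXCL9	CXCL10	HLA-DRA	GZMA	CCR5
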