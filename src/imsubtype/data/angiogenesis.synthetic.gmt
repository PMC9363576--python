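Angiogenesis	synthetic surrogate angiogenesis gene list	VEGFA	KDR	FLT1	PECAM1	CDH5	ANGPT2	TEK	ENG	CD34	VWF
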