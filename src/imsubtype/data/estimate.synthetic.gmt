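StromalSignature	synthetic surrogate stromal gene list	COL1A1	COL1A2	COL3A1	FAP	THY1	DCN	PDGFRB	ACTA2	FN1	LUM
ImmuneSignature	synthetic surrogate immune gene list	PTPRC	CD3E	CD8A	CD19	MS4A1	CD14	FCGR3A	GZMB	PRF1	IL7R
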