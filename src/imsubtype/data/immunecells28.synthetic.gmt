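Activated B cell	synthetic surrogate marker list	CD19	MS4A1	CD79A	CD79B	TNFRSF13B
Activated CD4 T cell	synthetic surrogate marker list	CD4	IL2RA	CD69	ICOS	CD28
Activated CD8 T cell	synthetic surrogate marker list	CD8A	CD8B	GZMB	PRF1	IFNG
Activated dendritic cell	synthetic surrogate marker list	CD83	CCR7	LAMP3	CD80	CD86
CD56bright natural killer cell	synthetic surrogate marker list	NCAM1	XCL1	XCL2	KLRC1	SELL
CD56dim natural killer cell	synthetic surrogate marker list	FCGR3A	KIR2DL1	KIR2DL3	KIR3DL1	GZMH
Central memory CD4 T cell	synthetic surrogate marker list	CCR7	SELL	IL7R	CD4	TCF7
Central memory CD8 T cell	synthetic surrogate marker list	CCR7	SELL	CD8A	IL7R	BCL2
Effector memory CD4 T cell	synthetic surrogate marker list	CD4	CCR5	CD40LG	IL2	PRDM1
Effector memory CD8 T cell	synthetic surrogate marker list	CD8A	GZMK	KLRG1	EOMES	CXCR3
Eosinophil	synthetic surrogate marker list	SIGLEC8	CCR3	IL5RA	EPX	PRG2
Gamma delta T cell	synthetic surrogate marker list	TRDC	TRGC1	TRGC2	KLRD1	NKG7
Immature B cell	synthetic surrogate marker list	CD19	CD38	IGHM	IGHD	VPREB3
Immature dendritic cell	synthetic surrogate marker list	CD1A	CD1C	ITGAX	CLEC10A	FCER1A
Macrophage	synthetic surrogate marker list	CD68	CD163	MRC1	MSR1	CSF1R
Mast cell	synthetic surrogate marker list	TPSAB1	TPSB2	CPA3	MS4A2	KIT
MDSC	synthetic surrogate marker list	ITGAM	CD33	ARG1	NOS2	S100A9
Memory B cell	synthetic surrogate marker list	CD27	CD19	MS4A1	TNFRSF13C	AIM2
Monocyte	synthetic surrogate marker list	CD14	FCN1	S100A8	S100A12	LYZ
Natural killer cell	synthetic surrogate marker list	NKG7	KLRD1	NCR1	GNLY	KLRF1
Natural killer T cell	synthetic surrogate marker list	CD3D	NCAM1	ZBTB16	KLRB1	IL2RB
Neutrophil	synthetic surrogate marker list	FCGR3B	CSF3R	CXCR2	FPR1	MPO
Plasmacytoid dendritic cell	synthetic surrogate marker list	CLEC4C	IL3RA	LILRA4	IRF7	TCF4
Regulatory T cell	synthetic surrogate marker list	FOXP3	IL2RA	CTLA4	IKZF2	TNFRSF18
T follicular helper cell	synthetic surrogate marker list	CXCR5	BCL6	ICOS	PDCD1	IL21
Type 1 T helper cell	synthetic surrogate marker list	TBX21	IFNG	IL12RB2	STAT4	CXCR3
Type 17 T helper cell	synthetic surrogate marker list	RORC	IL17A	IL23R	CCR6	IL22
Type 2 T helper cell	synthetic surrogate marker list	GATA3	IL4	IL5	IL13	CCR4
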