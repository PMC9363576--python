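HCK	synthetic surrogate list for the HCK myeloid metagene	HCK	MS4A4A	CD163	C1QA	C1QB	FCGR2A
IgG	synthetic surrogate list for the IgG plasma-cell metagene	IGHG1	IGHG3	IGKC	IGLC1	CD79A	MZB1
LCK	synthetic surrogate list for the LCK T-cell metagene	LCK	CD2	CD3D	CD3E	GZMA	GZMK
MHC-I	synthetic surrogate list for the MHC class I metagene	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2
MHC-II	synthetic surrogate list for the MHC class II metagene	HLA-DPA1	HLA-DPB1	HLA-DQA1	HLA-DQB1	HLA-DRA	CD74
Interferon	synthetic surrogate list for the interferon metagene	IFIT1	IFIT3	IFI44	MX1	OAS1	ISG15
STAT1	synthetic surrogate list for the STAT1 metagene	STAT1	IRF1	GBP1	CXCL9	CXCL10	PSMB9
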