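T_cells	na	CD3D	CD3E	CD3G	CD2	TRAC	IL7R	CD5
CD8_T_cells	na	CD8A	CD8B	EOMES	KLRK1
Cytotoxic_lymphocytes	na	GZMA	GZMB	GZMK	PRF1	GNLY	NKG7
NK_cells	na	NCR1	KIR2DL4	XCL1	XCL2	KLRD1
B_lineage	na	CD19	MS4A1	CD79A	CD79B	BLK
Monocytic_lineage	na	CD14	CD68	CSF1R	ITGAM	FCGR1A
Myeloid_dendritic_cells	na	ITGAX	CD1C	BATF3	CLEC9A	FLT3
Neutrophils	na	FCGR3B	CSF3R	S100A8	S100A9	FPR1
Endothelial_cells	na	PECAM1	VWF	CDH5	KDR	CLDN5
Fibroblasts	na	COL1A1	COL3A1	ACTA2	PDGFRB	FAP	DCN
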