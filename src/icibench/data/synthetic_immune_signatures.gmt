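APC_co_inhibition	na	PDCD1	CD274	CTLA4	LAG3	HAVCR2	TIGIT	BTLA	IDO1
APC_co_stimulation	na	CD80	CD86	CD40	TNFRSF4	TNFRSF9	TNFRSF18	ICOSLG
B_cells	na	CD19	MS4A1	CD79A	CD79B	BLK
CCR	na	CXCL9	CXCL10	CXCL11	CCL5	CXCL13	CCL4
CD8_T_cells	na	CD8A	CD8B	EOMES	KLRK1	GZMA	GZMB	GZMK	PRF1	GNLY	NKG7
Check_point	na	PDCD1	CD274	CTLA4	LAG3	HAVCR2	TIGIT	BTLA	IDO1
Cytolytic_activity	na	GZMA	GZMB	GZMK	PRF1	GNLY	NKG7
DCs	na	ITGAX	CD1C	BATF3	CLEC9A	FLT3
aDCs	na	ITGAX	CD1C	BATF3	CLEC9A	FLT3	CD80	CD86	CD40	TNFRSF4	TNFRSF9	TNFRSF18	ICOSLG
iDCs	na	ITGAX	CD1C	BATF3	CLEC9A	FLT3	CD14	CD68	CSF1R	ITGAM	FCGR1A
pDCs	na	ITGAX	CD1C	BATF3	CLEC9A	FLT3	IFNG	STAT1	IRF1	GBP1	GBP4	IFIT1	IFIT3
HLA	na	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	TAPBP	HLA-DRA	HLA-DRB1	HLA-DPA1	HLA-DPB1	HLA-DQA1	CD74
Inflammation_promoting	na	IL1B	IL6	TNF	PTGS2	NFKB1
Macrophages	na	CD14	CD68	CSF1R	ITGAM	FCGR1A	NOS2	IL12B	SOCS1	CXCL9	MRC1	CD163	MSR1	IL10
Mast_cells	na	TPSAB1	TPSB2	CPA3	MS4A2
MHC_class_I	na	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	TAPBP
Neutrophils	na	FCGR3B	CSF3R	S100A8	S100A9	FPR1
NK_cells	na	NCR1	KIR2DL4	XCL1	XCL2	KLRD1
Parainflammation	na	IL1B	IL6	TNF	PTGS2	NFKB1	IFNG	STAT1	IRF1	GBP1	GBP4	IFIT1	IFIT3
T_cell_co_inhibition	na	PDCD1	CD274	CTLA4	LAG3	HAVCR2	TIGIT	BTLA	IDO1	TOX	ENTPD1	CXCL13	LAYN
T_cell_co_stimulation	na	CD80	CD86	CD40	TNFRSF4	TNFRSF9	TNFRSF18	ICOSLG	CD3D	CD3E	CD3G	CD2	TRAC	IL7R	CD5
T_helper_cells	na	CD4	CD40LG	ICOS	CD28
Tfh	na	CXCR5	BCL6	PDCD1	ICOS
Th1_cells	na	IFNG	STAT1	IRF1	GBP1	GBP4	IFIT1	IFIT3	CD4	CD40LG	ICOS	CD28
Th2_cells	na	GATA3	IL4R	CCR4	STAT6
TIL	na	CD3D	CD3E	CD3G	CD2	TRAC	IL7R	CD5	CD19	MS4A1	CD79A	CD79B	BLK	NCR1	KIR2DL4	XCL1	XCL2	KLRD1
Treg	na	FOXP3	IL2RA	IKZF2	CCR8
Type_I_IFN_response	na	IFNG	STAT1	IRF1	GBP1	GBP4	IFIT1	IFIT3
Type_II_IFN_response	na	IFNG	STAT1	IRF1	GBP1	GBP4	IFIT1	IFIT3	CXCL9	CXCL10	CXCL11	CCL5	CXCL13	CCL4
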