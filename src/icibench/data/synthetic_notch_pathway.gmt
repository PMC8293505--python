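NOTCH_activated	activated	NOTCH1	NOTCH2	NOTCH3	NOTCH4	JAG1	JAG2	DLL1	DLL3	DLL4	HES1	HES2	HES3	HES4	HES5	HES6	HES7	HEY1	HEY2	HEYL	MAML1	MAML2	MAML3	RBPJ	RBPJL	ADAM10	ADAM17	PSEN1	PSEN2	PSENEN	NCSTN	APH1A	APH1B	LFNG	MFNG	RFNG	DTX1	DTX2	DTX3	DTX3L	DTX4	NRARP	SNW1	CREBBP	EP300	KAT2A	KAT2B	MIB1	MIB2	LNX1	CNTN1
NOTCH_repressed	repressed	NUMB	NUMBL	FBXW7	ITCH	NEDD4	NEDD4L	DLK1	DLK2	CTBP1	CTBP2	HDAC1	HDAC2	SPEN	CIR1	NCOR1	NCOR2	TLE1	TLE2	TLE3	TLE4	DNER
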