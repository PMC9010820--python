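STROMAL_SIGNATURE	placeholder stromal/matrix marker set (editable; replace with a curated signature)	COL1A1	COL1A2	COL3A1	COL4A1	COL5A1	COL5A2	COL6A1	COL6A2	COL6A3	COL14A1	FN1	FBN1	FBLN1	FBLN2	FBLN5	LUM	DCN	BGN	VCAN	POSTN	THBS1	THBS2	SPARC	TAGLN	ACTA2	MYL9	PDGFRA	PDGFRB	FAP	THY1	VIM	MMP2	TIMP1	TIMP3	LOX	LOXL1	SERPINF1	SERPINE2	MXRA5	OGN	MFAP4	EMILIN1
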