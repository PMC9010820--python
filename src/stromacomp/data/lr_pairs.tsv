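ligand	receptor
TGFB1	TGFBR1
TGFB1	TGFBR2
TGFB2	TGFBR1
TGFB3	TGFBR2
PDGFA	PDGFRA
PDGFB	PDGFRB
VEGFA	KDR
VEGFA	FLT1
FGF2	FGFR1
FGF7	FGFR2
HGF	MET
EGF	EGFR
TGFA	EGFR
IGF1	IGF1R
IGF2	IGF2R
CXCL12	CXCR4
CCL2	CCR2
CCL5	CCR5
CXCL9	CXCR3
CXCL10	CXCR3
IL6	IL6R
IL1B	IL1R1
TNF	TNFRSF1A
IFNG	IFNGR1
CD274	PDCD1
CD80	CTLA4
CD86	CD28
ICAM1	ITGAL
VCAM1	ITGA4
FN1	ITGA5
COL1A1	ITGA1
COL1A1	DDR1
LAMB1	ITGA6
THBS1	CD47
THBS2	CD36
SPP1	CD44
MIF	CD74
JAG1	NOTCH1
DLL4	NOTCH1
WNT5A	FZD5
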