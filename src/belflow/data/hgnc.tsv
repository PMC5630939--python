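id	preferred_name	synonyms	namespace
CYP4A11	CYP4A11	cytochrome P450 4A11	HGNC
MMP9	MMP9	matrix metallopeptidase 9|gelatinase B	HGNC
VEGFA	VEGFA	vascular endothelial growth factor A	HGNC
CD40LG	CD40LG	CD40 ligand|CD154	HGNC
CCL2	CCL2	MCP-1	HGNC
CCL5	CCL5	RANTES	HGNC
COL1A1	COL1A1	collagen type I alpha 1	HGNC
TIMP1	TIMP1	tissue inhibitor of metalloproteinase 1	HGNC
ETS2	ETS2		HGNC
ABL1	ABL1		HGNC
FGF2	FGF2	basic fibroblast growth factor	HGNC
THBS1	THBS1	thrombospondin 1	HGNC
HMGB1	HMGB1	high mobility group box 1	HGNC
COL4A3	COL4A3		HGNC
MMP2	MMP2	gelatinase A	HGNC
MMP3	MMP3	stromelysin 1	HGNC
MMP12	MMP12	macrophage elastase	HGNC
MMP13	MMP13		HGNC
TIMP2	TIMP2		HGNC
APOE	APOE	apolipoprotein E	HGNC
APOB	APOB		HGNC
LDLR	LDLR	LDL receptor	HGNC
PCSK9	PCSK9		HGNC
ABCA1	ABCA1		HGNC
SCARB1	SCARB1		HGNC
CD36	CD36		HGNC
MSR1	MSR1		HGNC
LPL	LPL	lipoprotein lipase	HGNC
NOS3	NOS3	endothelial nitric oxide synthase|eNOS	HGNC
NOS2	NOS2	iNOS	HGNC
PTGS2	PTGS2	cyclooxygenase 2|COX-2	HGNC
ALOX5	ALOX5	5-lipoxygenase	HGNC
ALOX15	ALOX15		HGNC
ICAM1	ICAM1	intercellular adhesion molecule 1	HGNC
VCAM1	VCAM1	vascular cell adhesion molecule 1	HGNC
SELE	SELE	E-selectin	HGNC
SELP	SELP	P-selectin	HGNC
PECAM1	PECAM1	CD31	HGNC
IL1B	IL1B	interleukin-1 beta	HGNC
IL6	IL6	interleukin-6	HGNC
IL10	IL10	interleukin-10	HGNC
IL18	IL18		HGNC
TNF	TNF	tumor necrosis factor alpha|TNF-alpha	HGNC
IFNG	IFNG	interferon gamma	HGNC
TGFB1	TGFB1	transforming growth factor beta 1	HGNC
CSF1	CSF1	M-CSF	HGNC
CSF2	CSF2	GM-CSF	HGNC
CXCL1	CXCL1		HGNC
CXCL8	CXCL8	interleukin-8	HGNC
CXCR4	CXCR4		HGNC
CCR2	CCR2		HGNC
CCR5	CCR5		HGNC
CD4	CD4		HGNC
CD8A	CD8A		HGNC
CD68	CD68		HGNC
CD40	CD40		HGNC
FOXP3	FOXP3		HGNC
TLR2	TLR2		HGNC
TLR4	TLR4		HGNC
MYD88	MYD88		HGNC
NFKB1	NFKB1		HGNC
RELA	RELA	p65	HGNC
STAT3	STAT3		HGNC
STAT1	STAT1		HGNC
JAK2	JAK2		HGNC
AKT1	AKT1		HGNC
MAPK1	MAPK1	ERK2	HGNC
MAPK8	MAPK8	JNK1	HGNC
PIK3CA	PIK3CA		HGNC
PTEN	PTEN		HGNC
TP53	TP53	p53	HGNC
CDKN2A	CDKN2A		HGNC
MYC	MYC		HGNC
FOS	FOS		HGNC
JUN	JUN		HGNC
PPARG	PPARG	PPAR gamma	HGNC
PPARA	PPARA		HGNC
NR1H3	NR1H3	LXR alpha	HGNC
SREBF2	SREBF2		HGNC
HMGCR	HMGCR	HMG-CoA reductase	HGNC
CETP	CETP		HGNC
PON1	PON1	paraoxonase 1	HGNC
MPO	MPO	myeloperoxidase	HGNC
NOX4	NOX4		HGNC
CYBB	CYBB	NOX2	HGNC
SOD1	SOD1		HGNC
SOD2	SOD2		HGNC
CAT	CAT	catalase gene	HGNC
GPX1	GPX1		HGNC
HMOX1	HMOX1	heme oxygenase 1	HGNC
NFE2L2	NFE2L2	NRF2	HGNC
EDN1	EDN1	endothelin 1	HGNC
AGT	AGT	angiotensinogen	HGNC
AGTR1	AGTR1	AT1 receptor	HGNC
ACE	ACE	angiotensin converting enzyme	HGNC
REN	REN		HGNC
NPPB	NPPB	BNP	HGNC
F2	F2	prothrombin	HGNC
F3	F3	tissue factor	HGNC
PLAT	PLAT	tPA	HGNC
PLAU	PLAU	uPA	HGNC
SERPINE1	SERPINE1	PAI-1	HGNC
FGA	FGA		HGNC
VWF	VWF	von Willebrand factor	HGNC
PLG	PLG	plasminogen	HGNC
ELN	ELN	elastin	HGNC
FBN1	FBN1	fibrillin 1	HGNC
ACTA2	ACTA2	smooth muscle actin	HGNC
MYH11	MYH11		HGNC
CNN1	CNN1	calponin 1	HGNC
TAGLN	TAGLN	SM22 alpha	HGNC
KLF4	KLF4		HGNC
KLF2	KLF2		HGNC
NOTCH1	NOTCH1		HGNC
DLL4	DLL4		HGNC
EFNB2	EFNB2		HGNC
KDR	KDR	VEGFR2	HGNC
FLT1	FLT1	VEGFR1	HGNC
ANGPT1	ANGPT1	angiopoietin 1	HGNC
ANGPT2	ANGPT2		HGNC
TEK	TEK	Tie2	HGNC
PDGFB	PDGFB		HGNC
PDGFRB	PDGFRB		HGNC
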