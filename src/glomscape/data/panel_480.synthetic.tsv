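gene	category
PODXL	marker:podocyte
NPHS1	marker:podocyte
NPHS2	marker:podocyte
PTPRQ	marker:podocyte
WT1	marker:podocyte
SYNPO	marker:podocyte
CLDN1	marker:PEC
PAX8	marker:PEC
CD44	marker:PEC
VCAM1	marker:PEC
AKAP12	marker:PEC
PROM1	marker:PEC
PDGFRB	marker:mesangial
ITGA8	marker:mesangial
GATA3	marker:mesangial
MYL9	marker:mesangial
TAGLN	marker:mesangial
REN	marker:mesangial
PECAM1	marker:endothelial
CDH5	marker:endothelial
EMCN	marker:endothelial
FLT1	marker:endothelial
KDR	marker:endothelial
EHD3	marker:endothelial
GPX3	marker:proximal_tubule
LRP2	marker:proximal_tubule
CUBN	marker:proximal_tubule
SLC34A1	marker:proximal_tubule
SLC13A3	marker:proximal_tubule
MIOX	marker:proximal_tubule
SLC12A1	marker:TAL
UMOD	marker:TAL
CLDN16	marker:TAL
KCNJ1	marker:TAL
CLDN10	marker:TAL
ESRRB	marker:TAL
AQP2	marker:collecting_duct
AQP3	marker:collecting_duct
SCNN1G	marker:collecting_duct
FXYD4	marker:collecting_duct
HSD11B2	marker:collecting_duct
AVPR2	marker:collecting_duct
DCN	marker:fibroblast
PDGFRA	marker:fibroblast
C7	marker:fibroblast
FBLN1	marker:fibroblast
MEG3	marker:fibroblast
SFRP2	marker:fibroblast
LYZ	marker:macrophage
CD163	marker:macrophage
CD68	marker:macrophage
C1QA	marker:macrophage
C1QB	marker:macrophage
MRC1	marker:macrophage
CD3D	marker:T_cell
CD3E	marker:T_cell
CD3G	marker:T_cell
TRAC	marker:T_cell
CD2	marker:T_cell
IL7R	marker:T_cell
MS4A1	marker:B_cell
CD79A	marker:B_cell
CD79B	marker:B_cell
CD19	marker:B_cell
BANK1	marker:B_cell
TNFRSF13B	marker:B_cell
MZB1	marker:plasma_cell
IGKC	marker:plasma_cell
JCHAIN	marker:plasma_cell
DERL3	marker:plasma_cell
XBP1	marker:plasma_cell
SDC1	marker:plasma_cell
PDGFA	pathway:PDGF
PDGFB	pathway:PDGF
PDGFC	pathway:PDGF
PDGFD	pathway:PDGF
STAT1	pathway:PDGF
STAT3	pathway:PDGF
PIK3R1	pathway:PDGF
PLCG1	pathway:PDGF
TGFB1	pathway:TGFB
TGFB2	pathway:TGFB
TGFB3	pathway:TGFB
TGFBR1	pathway:TGFB
TGFBR2	pathway:TGFB
SMAD3	pathway:TGFB
SMAD7	pathway:TGFB
SERPINE1	pathway:TGFB
JUNB	pathway:TGFB
SKIL	pathway:TGFB
COL1A1	fibrosis
COL4A1	fibrosis
FN1	fibrosis
LUM	fibrosis
TIMP1	fibrosis
C3	panel
S100A9	panel
S100A8	panel
S100A12	panel
FCN1	panel
VCAN	panel
CD14	panel
ITGAM	panel
ITGAX	panel
FCGR3A	panel
FCGR2A	panel
FCGR1A	panel
CD1C	panel
CLEC9A	panel
LILRA4	panel
IRF7	panel
IRF8	panel
TCF4	panel
NKG7	panel
GNLY	panel
GZMA	panel
GZMB	panel
GZMK	panel
PRF1	panel
KLRD1	panel
KLRB1	panel
NCAM1	panel
CD4	panel
CD8A	panel
CD8B	panel
CD28	panel
CTLA4	panel
PDCD1	panel
CD274	panel
LAG3	panel
HAVCR2	panel
TIGIT	panel
ICOS	panel
CD27	panel
CD40	panel
CD40LG	panel
IL2RA	panel
IL2RB	panel
IL1B	panel
IL2	panel
IL4	panel
IL6	panel
IL10	panel
IL15	panel
IL18	panel
IL32	panel
IL1RN	panel
IL1R1	panel
IL18R1	panel
IL6R	panel
IL6ST	panel
TNF	panel
TNFAIP3	panel
TNFRSF1A	panel
TNFRSF1B	panel
FAS	panel
FASLG	panel
IFNG	panel
IFNGR1	panel
IFNGR2	panel
IFNAR1	panel
IFNAR2	panel
CCL2	panel
CCL3	panel
CCL4	panel
CCL5	panel
CCL19	panel
CCL21	panel
CXCL1	panel
CXCL2	panel
CXCL9	panel
CXCL10	panel
CXCL11	panel
CXCL12	panel
CXCL13	panel
CXCL14	panel
CCR2	panel
CCR5	panel
CCR7	panel
CXCR3	panel
CXCR4	panel
CXCR5	panel
CXCR6	panel
HLA-A	panel
HLA-B	panel
HLA-C	panel
HLA-DRA	panel
HLA-DRB1	panel
HLA-DPA1	panel
HLA-DPB1	panel
HLA-DQA1	panel
HLA-DQB1	panel
B2M	panel
IFI6	panel
IFI27	panel
IFI44	panel
IFI44L	panel
IFIT1	panel
IFIT3	panel
ISG15	panel
MX1	panel
MX2	panel
OAS1	panel
OAS2	panel
OAS3	panel
STAT2	panel
SOCS1	panel
SOCS3	panel
JAK1	panel
JAK2	panel
JAK3	panel
TYK2	panel
STAT4	panel
STAT5A	panel
STAT5B	panel
NFKB1	panel
NFKBIA	panel
RELA	panel
RELB	panel
REL	panel
TRAF1	panel
TRAF3	panel
MYD88	panel
TLR2	panel
TLR4	panel
TLR7	panel
TLR9	panel
NLRP3	panel
CASP1	panel
C1S	panel
C1R	panel
C2	panel
C4A	panel
C4B	panel
C5	panel
C6	panel
C9	panel
CFB	panel
CFH	panel
CFI	panel
COL1A2	panel
COL3A1	panel
COL4A2	panel
COL4A3	panel
COL4A4	panel
COL4A5	panel
COL5A1	panel
COL6A1	panel
COL6A3	panel
COL15A1	panel
COL18A1	panel
SPARC	panel
POSTN	panel
TNC	panel
VIM	panel
FBN1	panel
ELN	panel
MMP2	panel
MMP7	panel
MMP9	panel
MMP14	panel
TIMP2	panel
TIMP3	panel
PLOD2	panel
LOX	panel
LOXL2	panel
CCN2	panel
CCN1	panel
SLC3A1	panel
SLC7A9	panel
SLC22A6	panel
SLC22A8	panel
SLC5A2	panel
SLC5A12	panel
SLC16A9	panel
SLC7A13	panel
AQP1	panel
AQP6	panel
ATP6V0D2	panel
ATP6V1G3	panel
SLC4A1	panel
SLC26A4	panel
SLC26A7	panel
CLCNKA	panel
CLCNKB	panel
BSND	panel
CALB1	panel
PVALB	panel
TRPV5	panel
SLC8A1	panel
SCNN1A	panel
SCNN1B	panel
NR3C2	panel
FXYD2	panel
PTH1R	panel
PLA2R1	panel
PTPRO	panel
MAGI2	panel
CD2AP	panel
TJP1	panel
ACTN4	panel
MYO1E	panel
PODN	panel
VWF	panel
PLVAP	panel
ENG	panel
TEK	panel
TIE1	panel
ESAM	panel
CLDN5	panel
RAMP2	panel
RAMP3	panel
SOX17	panel
SOX18	panel
CD34	panel
MCAM	panel
NOTCH4	panel
JAG1	panel
DLL4	panel
NOTCH1	panel
HES1	panel
HEY1	panel
FGF2	panel
FGF7	panel
FGFR1	panel
FGFR2	panel
EGF	panel
EGFR	panel
HBEGF	panel
TGFA	panel
VEGFA	panel
VEGFB	panel
VEGFC	panel
FLT4	panel
NRP1	panel
NRP2	panel
ANGPT1	panel
ANGPT2	panel
MAPK1	panel
MAPK3	panel
AKT1	panel
AKT2	panel
PIK3CA	panel
MTOR	panel
RPS6KB1	panel
MKI67	panel
TOP2A	panel
CCNB1	panel
CCND1	panel
CCNE1	panel
CDK1	panel
CDK4	panel
CDK6	panel
CDKN1A	panel
CDKN1B	panel
CDKN2A	panel
PCNA	panel
AURKA	panel
AURKB	panel
BUB1	panel
PLK1	panel
E2F1	panel
FOXM1	panel
HAVCR1	panel
LCN2	panel
SPP1	panel
CST3	panel
CLU	panel
APOE	panel
IGFBP7	panel
SOX9	panel
KRT7	panel
KRT8	panel
KRT18	panel
KRT19	panel
CDH1	panel
CDH2	panel
EPCAM	panel
SNAI1	panel
SNAI2	panel
TWIST1	panel
ZEB1	panel
ZEB2	panel
BAX	panel
BCL2	panel
BCL2L1	panel
MCL1	panel
CASP3	panel
CASP8	panel
TP53	panel
MDM2	panel
GAPDH	panel
ACTB	panel
OSMR	panel
LIF	panel
LIFR	panel
CSF1	panel
CSF1R	panel
CSF2	panel
CSF2RA	panel
CSF3R	panel
FLT3	panel
KIT	panel
KITLG	panel
APOL1	panel
SSBP1	panel
GREM1	panel
BMP2	panel
BMP4	panel
BMP7	panel
WNT4	panel
WNT5A	panel
CTNNB1	panel
LEF1	panel
AXIN2	panel
DKK1	panel
SHH	panel
GLI1	panel
SELL	panel
SELP	panel
SELE	panel
ICAM1	panel
ITGB1	panel
ITGB2	panel
ITGA4	panel
ITGAL	panel
CD69	panel
CD38	panel
CD5	panel
CD6	panel
CD7	panel
FOXP3	panel
IKZF2	panel
RORC	panel
TBX21	panel
GATA2	panel
RUNX1	panel
RUNX3	panel
BACH2	panel
PRDM1	panel
IRF4	panel
BATF	panel
TOX	panel
EOMES	panel
TCF7	panel
KLRG1	panel
CX3CR1	panel
CX3CL1	panel
S1PR1	panel
S1PR5	panel
AGT	panel
ACE	panel
AGTR1	panel
NPPA	panel
NPPB	panel
EDN1	panel
EDNRA	panel
EDNRB	panel
NOS3	panel
KLK1	panel
KNG1	panel
SLPI	panel
MUC1	panel
KRT5	panel
KRT14	panel
TP63	panel
SOX4	panel
JUN	panel
FOS	panel
FOSB	panel
EGR1	panel
ATF3	panel
HSPA1A	panel
HSPA5	panel
DDIT3	panel
XIAP	panel
ALB	panel
TTR	panel
APOA1	panel
TF	panel
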