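interaction_id,ligand_genes,receptor_genes,pathway,category
PDGFA_PDGFRA,PDGFA,PDGFRA,PDGF,secreted
PDGFB_PDGFRB,PDGFB,PDGFRB,PDGF,secreted
PDGFC_PDGFRA,PDGFC,PDGFRA,PDGF,secreted
PDGFD_PDGFRB,PDGFD,PDGFRB,PDGF,secreted
TGFB1_TGFBR,TGFB1,TGFBR1;TGFBR2,TGFb,secreted
TGFB2_TGFBR,TGFB2,TGFBR1;TGFBR2,TGFb,secreted
TGFB3_TGFBR,TGFB3,TGFBR1;TGFBR2,TGFb,secreted
VEGFA_KDR,VEGFA,KDR,VEGF,secreted
VEGFA_FLT1,VEGFA,FLT1,VEGF,secreted
CXCL12_CXCR4,CXCL12,CXCR4,CXCL,secreted
CCL2_CCR2,CCL2,CCR2,CCL,secreted
IL6_IL6R,IL6,IL6R;IL6ST,IL6,secreted
EGF_EGFR,EGF,EGFR,EGF,secreted
DLL4_NOTCH1,DLL4,NOTCH1,NOTCH,contact
JAG1_NOTCH1,JAG1,NOTCH1,NOTCH,contact
CX3CL1_CX3CR1,CX3CL1,CX3CR1,CX3C,secreted
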