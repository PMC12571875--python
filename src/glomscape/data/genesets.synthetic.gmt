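PDGF_SIGNALING	synthetic stand-in for the PDGFR-in-disease signaling set, supplemented with PDGF ligands and receptors	PDGFA	PDGFB	PDGFC	PDGFD	PDGFRA	PDGFRB	STAT1	STAT3	PIK3R1	PLCG1
TGFB_SIGNALING	synthetic stand-in for the hallmark TGF-beta signaling set	TGFB1	TGFB2	TGFB3	TGFBR1	TGFBR2	SMAD3	SMAD7	SERPINE1	JUNB	SKIL
FIBROSIS	extracellular-matrix / fibrosis score genes	COL1A1	COL4A1	FN1	LUM	TIMP1
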