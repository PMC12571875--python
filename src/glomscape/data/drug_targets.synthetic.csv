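drug_id,target_gene,action
nintedanib,PDGFRA,inhibitor
nintedanib,PDGFRB,inhibitor
nintedanib,KDR,inhibitor
nintedanib,FLT1,inhibitor
nintedanib,FGFR1,inhibitor
nintedanib,FGFR2,inhibitor
imatinib,PDGFRA,inhibitor
imatinib,PDGFRB,inhibitor
imatinib,KIT,inhibitor
sunitinib,PDGFRA,inhibitor
sunitinib,PDGFRB,inhibitor
sunitinib,KDR,inhibitor
sunitinib,FLT3,inhibitor
sunitinib,CSF1R,inhibitor
becaplermin,PDGFRB,agonist
olaratumab,PDGFRA,antagonist
seribantumab,EGFR,antagonist
fresolimumab,TGFB1,antagonist
fresolimumab,TGFB2,antagonist
fresolimumab,TGFB3,antagonist
galunisertib,TGFBR1,inhibitor
pirfenidone,TGFB1,inhibitor
vactosertib,TGFBR1,inhibitor
luspatercept,TGFB1,binder
luspatercept,TGFB2,binder
metformin,PRKAA1,activator
aspirin,PTGS1,inhibitor
aspirin,PTGS2,inhibitor
lisinopril,ACE,inhibitor
losartan,AGTR1,antagonist
prednisolone,NR3C1,agonist
rituximab,MS4A1,antagonist
tocilizumab,IL6R,antagonist
ruxolitinib,JAK1,inhibitor
ruxolitinib,JAK2,inhibitor
fostamatinib,SYK,inhibitor
fostamatinib,FLT3,inhibitor
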