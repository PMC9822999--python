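ligand,receptor,annotation
CD274,PDCD1,checkpoint
CD80,CTLA4,checkpoint
LGALS9,HAVCR2,checkpoint
PVR,TIGIT,checkpoint
CCL3,CCR5,chemokine
CCL4,CCR5,chemokine
CCL5,CCR5,chemokine
CXCL9,CXCR3,chemokine
CXCL10,CXCR3,chemokine
CXCL13,CXCR5,chemokine
CCL17,CCR4,chemokine
CCL22,CCR4,chemokine
CCL18,CCR8,chemokine
CSF1,CSF1R,cytokine
IL15,IL15RA,cytokine
IL10,IL10RA,cytokine
FLT3LG,FLT3,cytokine
IL21,IL21R,cytokine
IL13,IL13RA1,cytokine
TGFB1,TGFBR1,cytokine
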