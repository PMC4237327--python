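symbol,source
EGFR,cosmic-glioma
PDGFRA,cosmic-glioma
PDGFB,cosmic-glioma
MET,cosmic-glioma
PIK3CA,cosmic-glioma
PIK3R1,cosmic-glioma
PTEN,cosmic-glioma
TP53,cosmic-glioma
RB1,cosmic-glioma
NF1,cosmic-glioma
NF2,cosmic-glioma
CDK4,cosmic-glioma
CDK6,cosmic-glioma
CDKN2C,cosmic-glioma
MDM2,cosmic-glioma
MDM4,cosmic-glioma
IDH1,cosmic-glioma
IDH2,cosmic-glioma
ATRX,cosmic-glioma
CIC,cosmic-glioma
FUBP1,cosmic-glioma
BRAF,cosmic-glioma
FGFR1,cosmic-glioma
KRAS,other-tumour-types-addition
MYC,other-tumour-types-addition
CDKN2A(p16),other-tumour-types-addition
CDKN2A(p14),other-tumour-types-addition
CTNNB1(beta-catenin),other-tumour-types-addition
ERBB2(HER2),other-tumour-types-addition
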