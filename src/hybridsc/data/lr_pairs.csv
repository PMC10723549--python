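ligand,receptor,annotation
GAS6,AXL,tumor-hybrid growth arrest specific 6 / AXL receptor tyrosine kinase
CXCL12,CXCR4,chemokine axis implicated in homing and dissemination
LGALS9,P4HB,galectin 9 / prolyl 4-hydroxylase subunit beta
IGF1,IGF1R,insulin-like growth factor axis with hepatic ligand source
TYROBP,CD44,TYRO protein tyrosine kinase binding protein / CD44
APP,CD74,amyloid beta precursor protein / CD74
ANXA1,FPR1,annexin A1 / formyl peptide receptor 1
ANXA1,FPR3,annexin A1 / formyl peptide receptor 3
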