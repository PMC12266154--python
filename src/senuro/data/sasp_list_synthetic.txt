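# Synthetic stand-in for a SASP (senescence-associated secretory phenotype)
# protein list, one symbol per line.  Replace with a list exported from a
# SASP atlas of renal epithelial senescence for real analyses.
CLU
GDF15
TIMP1
IGFBP7
SERPINE1
MMP7
IL6
CXCL8
IGFBP3
TNFRSF10C
STC1
MIF
LGALS3
B2M
CST3
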