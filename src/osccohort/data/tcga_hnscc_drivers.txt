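# Canonical TCGA-HNSCC driver genes used for cohort overlap reporting
TP53
CDKN2A
EGFR
FAT1
NOTCH1
KMT2D
NSD1
CASP8
HRAS
FBXW7
CCND1
MYC
PIK3CA
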