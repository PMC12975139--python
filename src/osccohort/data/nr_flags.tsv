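gene	vdr	er	ar	role
ABCB1	Yes	Yes	Yes	Multidrug resistance
CAPN10	No	No	No	-
CD44	Yes	Yes	Yes	Tumor metastasis
CDC27	No	No	Yes	Tumor suppressor/oncogene
CHI3L1	Yes	Yes	Yes	Angiogenesis, proliferation, survival
CNN2	No	Yes	Yes	Regulates EGR1 expression
COMT	Yes	Yes	-	Estrogen metabolism
CTBP2	No	Yes	Yes	Corepressor of ER and AR
IGSF3	No	No	No	-
IL6	Yes	Yes	Yes	Anti-tumor immune response
IL6-AS1	No	No	No	-
MAPKAPK3	No	Yes	No	Tumor suppressive and promoting
MGST3	No	No	No	-
NAT2	Yes	Yes	Yes	Metabolizing carcinogens
NOS3	Yes	Yes	Yes	Angiogenesis and drug response
OPRM1	No	Yes	Yes	Opioid receptor
PADI2	Yes	Yes	Yes	Chemoradiotherapy resistance
SLC2A9	No	Yes	Yes	Tumor suppression
TBXT	No	No	No	-
TLR1	Yes	Yes	No	Tumor suppressive/promoting
VKORC1	Yes	Yes	No	Ferroptosis repressor
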