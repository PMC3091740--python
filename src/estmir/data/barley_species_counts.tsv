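species	m	k
Arabidopsis thaliana	207	43
Oryza sativa	415	102
Glycine max	79	15
Pinus taeda	38	6
Triticum aestivum	32	20
Physcomitrella patens	281	39
Populus trichocarpa	237	71
Chlamydomonas reinhardtii	84	2
Selaginella moellendorffii	64	12
Vitis vinifera	140	47
Brassica napus	44	19
Gossypium hirsutum	13	4
Medicago truncatula	46	8
Solanum lycopersicum	30	11
Sorghum bicolor	72	27
Zea mays	98	48
Brassica oleracea	7	2
Brassica rapa	19	8
Saccharum officinarum	16	11
Gossypium herbecium	1	0
Carica papaya	1	0
Vigna unguiculata	1	0
Lotus japonicus	2	0
Gossypium rammindii	2	2
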