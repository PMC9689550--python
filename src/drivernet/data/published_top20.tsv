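# Published top-20 genes per centrality metric, one metric per line.
# Rows are kept exactly as printed: the degree row runs "CCNA2 CDK1"
# together without a comma, and the betweenness row prints the misprint
# "REBBP" for CREBBP (resolved via symbol_aliases.tsv).
degree	TP53, CCNA2 CDK1, CCNB1, BUB1, TOP2A, BRCA1, BUB1B, KIF11, NCAPG, CCNB2, KIF23, CENPE, KIF20A, KIF4A, ASPM, TPX2, DLGAP5, CCND1, KIF15
closeness	TP53, BRCA1, CCNA2, MYC, CCND1, CDK1, AKT1, CCNB1, CDKN2A, TOP2A, BUB1, ATM, ESR1, CREBBP, PTEN, EGFR, RAD51, BUB1B, MDM2, ERBB2
betweenness	TP53, BRCA1, CCNA2, CDK1, REBBP, SMAD4, AKT1, CCND1, ESR1, CCNB1, MYC, PTEN, STAG2, CNOT3, TOP2A, PIK3CA, HRAS, ATM, BUB1, KIF23
eigenvector	CCNA2, CDK1, BUB1, CCNB1, TOP2A, KIF11, BUB1B, NCAPG, KIF20A, CENPE, KIF4A, ASPM, CCNB2, TPX2, MELK, DLGAP5, KIF23, KIF15, CEP55, NUSAP1
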