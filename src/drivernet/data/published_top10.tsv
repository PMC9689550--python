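# Published top-10 genes per centrality metric, one metric per line.
degree	TP53, CCNA2, CDK1, CCNB1, BUB1, TOP2A, BRCA1, BUB1B, KIF11, NCAPG
closeness	TP53, BRCA1, CCNA2, MYC, CCND1, CDK1, AKT1, CCNB1, CDKN2A, TOP2A
betweenness	TP53, BRCA1, CCNA2, CDK1, CREBBP, SMAD4, AKT1, CCND1, ESR1, CCNB1
eigenvector	CCNA2, CDK1, BUB1, CCNB1, TOP2A, KIF11, BUB1B, NCAPG, KIF20A, CENPE
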