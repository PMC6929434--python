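# Local compound-identifier lookup table: id<TAB>smiles<TAB>name
# A small offline excerpt; users can point --kegg-table at a fuller file.
C00078	N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O	L-tryptophan
C00079	N[C@@H](Cc1ccccc1)C(=O)O	L-phenylalanine
C00082	N[C@@H](Cc1ccc(O)cc1)C(=O)O	L-tyrosine
C00033	CC(=O)O	acetate
C00383	OC(=O)CC(=O)O	malonate
C02679	CCCCCCCCCCCC(=O)O	dodecanoic acid
C00493	OC(=O)C1=C[C@@H](O)[C@@H](O)[C@H](O)C1	shikimate
C00031	C([C@@H]1[C@H]([C@@H]([C@H]([C@H](O1)O)O)O)O)O	D-glucose
C01672	NCCCCCN	cadaverine
C00423	OC(=O)/C=C/c1ccccc1	trans-cinnamate
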