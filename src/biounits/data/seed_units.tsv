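# Default seed library of biosynthetic starting materials.
# Columns: id<TAB>role<TAB>smiles<TAB>seed_id<TAB>rules (comma-separated; empty for seeds)
# Roles here are restricted to BBU (basic unit) and PBU (preferential unit);
# derivative units are generated at build time by the transformation rules.
glycine	BBU	NCC(=O)O
L-alanine	BBU	C[C@@H](N)C(=O)O
L-valine	BBU	CC(C)[C@@H](N)C(=O)O
L-leucine	BBU	CC(C)C[C@@H](N)C(=O)O
L-isoleucine	BBU	CC[C@H](C)[C@@H](N)C(=O)O
L-serine	BBU	OC[C@@H](N)C(=O)O
L-cysteine	BBU	SC[C@@H](N)C(=O)O
L-aspartate	BBU	OC(=O)C[C@@H](N)C(=O)O
L-glutamate	BBU	OC(=O)CC[C@@H](N)C(=O)O
L-lysine	BBU	NCCCC[C@@H](N)C(=O)O
L-arginine	BBU	NC(=N)NCCC[C@@H](N)C(=O)O
L-phenylalanine	BBU	N[C@@H](Cc1ccccc1)C(=O)O
L-tyrosine	BBU	N[C@@H](Cc1ccc(O)cc1)C(=O)O
L-tryptophan	BBU	N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O
L-proline	BBU	OC(=O)[C@@H]1CCCN1
L-histidine	BBU	N[C@@H](Cc1c[nH]cn1)C(=O)O
L-methionine	BBU	CSCC[C@@H](N)C(=O)O
L-threonine	BBU	C[C@@H](O)[C@H](N)C(=O)O
acetate-C2	BBU	CC(=O)O
malonate	BBU	OC(=O)CC(=O)O
cinnamate	BBU	OC(=O)/C=C/c1ccccc1
p-coumarate	BBU	OC(=O)/C=C/c1ccc(O)cc1
cadaverine	BBU	NCCCCCN
putrescine	BBU	NCCCCN
prenol-C5	BBU	CC(C)=CCO
chorismate	BBU	C1=C[C@H](O)[C@@H](OC(=C)C(=O)O)C=C1C(=O)O
alpha-D-glucose	PBU	C([C@@H]1[C@H]([C@@H]([C@H]([C@H](O1)O)O)O)O)O
beta-D-galactose	PBU	C([C@@H]1[C@@H]([C@@H]([C@H]([C@@H](O1)O)O)O)O)O
alpha-L-rhamnose	PBU	C[C@H]1[C@@H]([C@H]([C@H]([C@@H](O1)O)O)O)O
D-glucuronate	PBU	O[C@@H]1O[C@H](C(=O)O)[C@@H](O)[C@H](O)[C@H]1O
alpha-L-arabinose	PBU	O[C@@H]1CO[C@H](O)[C@H](O)[C@H]1O
shikimate	PBU	OC(=O)C1=C[C@@H](O)[C@@H](O)[C@H](O)C1
betalamate	PBU	OC(=O)C1CC(=CC=O)C=C(C(=O)O)N1
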