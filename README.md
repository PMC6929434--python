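# biounits

Knowledge-based disassembly of natural-product structures into
**biosynthetic units** (BUs) — the substructures left behind by the
starting materials of secondary metabolism (amino acids, sugars,
shikimate-pathway acids, acetate units, diamines, ...). Given a target
molecule, the workflow proposes which starting materials it was
biosynthesized from and which bonds were formed along the way, the first
step in reconstructing a biosynthetic pathway. A genetic-algorithm
baseline that optimizes cut bonds by fingerprint similarity, with no
structural knowledge, is included for comparison.

Intended users: natural-product chemists and synthetic biologists who
want starting-material hypotheses for a metabolite, and method
developers who need a reproducible, fully synthetic test bed for
disassembly algorithms.

## The method

A **biosynthetic unit library (BUL)** is built from curated seed
structures: *basic units* (BBUs, key biosynthetic intermediates),
their *derivative units* (DBUs, each BBU after one of 14 chemical
transformation rules: dehydroxylation, decarboxylation, deamination,
decarbonylation, oxidative deamination, amino transfer, denitration,
dephosphorylation, (de)hydrogenation, CoA removal, denucleotidylation,
ring opening, ring closure, hydrolysis), and *preferential units*
(PBUs: five monosaccharide residues, a shikimate and a betalamate
moiety) that are matched with priority because they persist unchanged
downstream of their attachment.

For a query molecule the workflow:

1. parses the input (SMILES, InChI, Molfile V2000, or a compound id
   resolved through a local table);
2. builds the **query-specific BUL**: every library unit contained in
   the query under chirality-aware, aromatic-bond-strict substructure
   matching, sorted by decreasing heavy-atom count *N*. For
   aromatic-rich queries (≥ 17 aromatic bonds) units rejected only
   because a ring aromatized are *rescued* via a relaxed-bond-order
   MCS when the ambiguity ratio is ≤ 0.2;
3. builds the **fragment network** by repeated digestion: an embedded
   unit's boundary bonds are cut in one event, and unresolved fragments
   are digested again until every leaf equals a unit. Stage one digests
   the whole molecule with the PBUs plus the largest ⌈N/2⌉ units;
4. enumerates unit **combinations** with a breadth-first queue,
   replacing parents by their children while the fragment count stays
   within `limit = ⌈N_atoms/k⌉` (k = 1, 3, 4, 6 by molecule size), and
   sorts candidates by largest fragment (descending), then fragment
   count (ascending);
5. reports the result as JSON/TSV plus an SVG in which each fragment of
   the best combination is colour-coded and labelled with its unit.

The GA baseline encodes cut bonds as a binary genome and maximizes the
minimum fragment-to-library Tanimoto similarity (Morgan fingerprints,
radius 2, 1024 bits; population 300, crossover 0.80, mutation 0.005,
200 generations, top-5 reported).

## Worked example

Disassemble a synthetic cinnamate glucoside with the default library
(26 seed units + 7 PBUs, expanded to 222 units by the transformation
rules):

```bash
biounits disassemble "O=C(O)/C=C/c1ccccc1O[C@H]1O[C@H](CO)[C@@H](O)[C@H](O)[C@H]1O" --out demo
```

prints

```
status: ok
best (2 fragments): OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O (alpha-D-glucose), O=C(O)/C=C/c1ccccc1 (cinnamate)
outputs written to demo/
```

The glucoside is recognized as an α-D-glucose residue (matched
preferentially, with the anomeric configuration respected — a
β-glucose unit would *not* match) attached to a cinnamate unit; the
digested bond is the glycosidic linkage. `demo/` then contains
`report.json` (query library, all candidates, per-atom colours),
`candidates.tsv`, `result.svg` (the colour-coded depiction) and
`network.json` (the fragment network).

Other entry points: `biounits ga-baseline <smiles>` runs the
genetic-algorithm comparison and `biounits build-bul seeds.tsv` derives
and saves a library from your own seed file (TSV:
`id  role  smiles  seed_id  rules`).

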