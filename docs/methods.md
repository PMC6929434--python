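# Methods

This note records the model behind `biounits`, the parameters that
matter, the numerical and design choices made where the method left
room, and what the synthetic test bed does and does not demonstrate.

## Model and assumptions

The central assumption is that a secondary metabolite is an assembly of
residues of its biosynthetic starting materials, joined by bonds formed
during biosynthesis, and that those residues can be recovered by
cutting bonds — i.e. that tailoring between starting material and
product is limited to the small transformations encoded in the rule
set, not skeletal rearrangement. Molecules whose biosynthesis
rearranges rings, eliminates atoms from a unit, or desaturates a unit
in many alternative positions (terpenoids, polyketides with extensive
reduction) fall outside the model; the fragment-count limit (below)
deliberately excludes long fatty-acid-like chains whose answer would be
many minimal C2 units.

A disassembly is a partition of the query's heavy atoms into fragments,
each *identical* to a library unit once the open valences created by
cutting are filled with hydrogen. Identity is stereo-aware canonical
SMILES equality; fragments carry attachment flags (atom-map number 1)
at cut positions, which participate in the fragment-network node
identity but are stripped for unit-identity tests, so a fragment with a
stub still equals a stub-free unit.

## Matching semantics

Unit containment uses chirality-aware substructure matching: a unit
stereocentre with a specified configuration must match it; unspecified
centres match either. Bond kinds are strict — an aromatic bond never
matches a localized double bond — which mirrors how the underlying
matcher treats Kekulé versus aromatic forms. Atom aromaticity flags are
not compared on their own (a methyl carbon may map onto a ring carbon
through a single bond); the tests' independent subgraph-isomorphism
oracle encodes exactly this contract.

Because aromatization is common in biosynthesis, strict matching
falsely rejects units whose ring system became aromatic in the product.
For queries with at least `aromatic_rescue_threshold` (default 17)
aromatic bonds, each rejected unit is re-tested with a maximum common
substructure search under relaxed bond-order comparison. The unit is
*rescued* when (a) the MCS covers every unit atom and (b) the ratio of
ambiguous bonds to conjugated double bonds is at most
`ambiguity_ratio_max` (default 0.2). Counting sides are a design
choice the ratio definition leaves open; here an **ambiguous bond** is
an MCS bond whose aromatic flag differs between target and unit side,
and the **denominator** counts target-side MCS bonds that are
conjugated and double or aromatic (aromatic bonds are conjugated, and
excluding them would make the ratio ≥ 1 for precisely the aromatization
cases the rescue exists for). A 0/0 ratio passes; a positive numerator
over zero fails. Rescued units enter digestion through their MCS
placement, since no exact embedding exists.

## Fragmentation and search

A digestion event cuts *all* bonds with exactly one endpoint in the
embedded unit's atom set, so one event separates the unit from the
remainder(s). Stereo descriptors that referenced a cut bond are
dropped. Cuts that slice an aromatic ring (possible only for
MCS-placed rescued units) produce unsanitizable fragments; such events
are skipped with a log message rather than propagated.

Network construction is two-stage. Stage A digests the root with every
preferential unit plus the largest ⌈N/2⌉ non-preferential units of the
query-specific library (N = library size). Stage B digests every
unresolved leaf against the whole query-specific library until nothing
changes; the budget gates stage A only, because a leaf must be allowed
to meet any unit it still contains, and the preferential-unit fragments
are already resolved and never re-digested. Fragments are
deduplicated by occurrence (the query-atom set they cover) so that atom
provenance is exact; structurally identical occurrences share one
canonical key, which is the node identity of the exported graph.

By default one embedding per (fragment, unit) pair is explored — the
first match found — which is cheap but can miss decompositions in
symmetric molecules where the first placement straddles two true
residues. Raising `max_embeddings` enumerates distinct matched-atom
sets and removes this failure mode at combinatorial cost.

Candidate enumeration is a breadth-first queue over fragment multisets:
pop a combination, emit it if every fragment equals a unit, and push
each single-parent-to-children replacement whose fragment count stays
within `limit = ⌈N_atoms/k⌉` with k = 1 (N ≤ 4), 3 (5–24), 4 (25–53),
6 (N ≥ 54). Combinations are deduplicated by their multiset of
fragment keys. Candidates are sorted by largest fragment (descending),
fragment count (ascending), then the lexicographic key tuple so that
ordering is deterministic; when several units are identical to one
fragment, all are recorded and the reported one is chosen by role
precedence (preferential > basic > derivative), then id.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `aromatic_rescue_threshold` | 17 bonds | minimum aromatic-bond count of the query to attempt MCS rescue |
| `ambiguity_ratio_max` | 0.2 | maximum ambiguous/conjugated-double ratio for a rescue |
| `max_embeddings` | 1 | embeddings explored per (fragment, unit); 1 = first match only |
| `mcs_timeout` | 10 s | per-call MCS budget; timeout skips the rescue for that unit |
| `max_network_nodes` / `max_digestion_depth` | 10 000 / 12 | hard caps; exceeding either is a loud "search space exceeded" outcome |
| GA: population / crossover / mutation / generations | 300 / 0.80 / 0.005 / 200 | baseline optimizer settings |
| GA: fingerprint | Morgan r=2, 1024 bits | similarity basis of the fitness |

## Library construction choices

The shipped seed set (26 basic units: the proteinogenic amino acids
most relevant to alkaloid and phenylpropanoid pathways, shikimate and
chorismate, acetate and malonate, cinnamate and p-coumarate,
cadaverine and putrescine, a C5 prenol) is a deliberately small,
documented default — the algorithm, not the curation, is the artifact —
and users supply their own seed TSV for serious use. The seven
preferential units are glucose, galactose, rhamnose, glucuronate,
arabinose, shikimate and betalamate; the exact choice of the five
monosaccharides (and their anomeric forms) is a configurable default,
as common glycoside residues in plant metabolism.

Rule products are generated at depth 1 (each rule applied once to each
seed, no chaining): with the default seeds this yields 222 units after
deduplication, consistent with a roughly 2:1 derivative-to-seed ratio;
deeper chaining grows the library combinatorially while adding mostly
implausible units. Products smaller than 2 heavy atoms are discarded
(single atoms match everywhere and mean nothing biosynthetically).
Deduplication keeps the highest-precedence role. The exact structural
patterns of the 14 rules are not canonical chemistry-free choices;
each is a declarative reaction pattern documented in
`src/biounits/rules.py`, with the truncation rules (CoA and nucleotide
removal) keeping the acyl/core side and ring opening/closure bounded to
rings of size 5–7. "Denitration" ships disabled by default because
nitro groups are rare in the intended pathways and the rule is easy to
toggle (`enable_denitration`).

Charged/protonation forms are not normalized: seeds are stored neutral
and matched as drawn.

## GA baseline choices

The genome covers acyclic single non-aromatic bonds between heavy
atoms — the only cuts the knowledge-based fragmenter can make — with a
flag to widen it to all bonds. Survival and variation operators are
not dictated by the baseline's description, so conventional defaults
are used and recorded: size-3 tournament selection, one elite carried
over (making best fitness monotone), two-point crossover, per-gene bit
flip. All randomness flows from one integer seed; identical inputs and
seed give bit-identical top-5 genomes. A fitness of 1.0 means
fingerprint identity of every fragment with some unit, which is
necessary but not sufficient for structural identity.

## The synthetic test bed

Planted molecules are built by joining unit copies with new acyclic
single bonds at atoms with free valence, recording the junction bonds;
cutting exactly those bonds provably regenerates the units. The suite
(14 fixtures) covers single-unit identity, chains of 2–6 units, two
glycosides (exercising preferential sugar matching and anomer
discrimination), an aromatic-rich biaryl with a rescue-requiring
distractor unit, a symmetric diamide-like target with repeated units,
and a dodecanoic-acid analogue whose six-C2 answer exceeds the default
fragment limit (⌈14/3⌉ = 5) and is therefore reported as "no
disassembly found" unless the limit is raised.

What passing this suite shows: the matching semantics, budget and limit
formulas, fragmentation bookkeeping (atom conservation at every event
and in every emitted candidate), ranking, rescue trigger and exclusion
behaviour all work as specified, and on small fixtures the queue search
agrees exactly with exhaustive enumeration of all cut-bond subsets.
What it does not show: performance on real natural products, whose
junctions are not random single bonds (amide, ester, and C-glycosidic
linkages have different chemistry than the generator's generic joins),
whose units overlap ambiguously, and whose libraries are hundreds of
units curated against real pathway maps.

## Degenerate inputs and outcomes

Empty input, unparseable text, unknown compound ids and structures with
undefined R-groups raise typed errors naming the failing stage. A
query containing no library unit is a reported outcome ("no units
matched"), as are "no disassembly found" (empty candidate list, CLI
exit code 3) and "search space exceeded" (a cap was hit, exit code 4);
none of these are crashes.
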