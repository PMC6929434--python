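"""Fragment network: embedding-guided bond digestion.

A *digestion* takes an embedding of a unit inside a fragment and cuts
every bond with exactly one endpoint in the embedded atom set, so one
split event yields the unit-shaped piece plus the remainder(s).  The
resulting parent -> children relationships form the fragment network,
rooted at the whole query molecule.  Construction has two stages:

* **Stage A** digests the root once per embedding of each selected
  unit.  Selection takes all preferential units plus the largest
  ``ceil(N/2)`` remaining units of the query-specific library (N being
  the library size) -- the unit budget that keeps enumeration tractable.
* **Stage B** repeatedly digests every unresolved leaf (a fragment not
  identical to any selected unit) against the selected units until all
  leaves resolve or no digestion makes progress.  Leaves nothing embeds
  into are marked dead ends.

Fragments are deduplicated by occurrence (the set of query atoms they
cover); structurally identical fragments share one canonical key, which
is the node identity in the exported key-level graph.  Atom provenance
is tracked so every event provably partitions its parent's atoms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from rdkit import Chem

from .chemgraph import canonical_key, mark_attachment, plain_key
from .config import DEFAULT_CONFIG, DisassemblerConfig
from .errors import ContractViolation, SearchSpaceExceeded
from .matching import Embedding, QueryLibrary, find_embeddings, mcs_with_ambiguity
from .search import unit_budget

log = logging.getLogger(__name__)

ORIG_IDX_PROP = "origIdx"
_ROLE_ORDER = {"PBU": 0, "BBU": 1, "DBU": 2}


@dataclass(frozen=True)
class Fragment:
    """One occurrence of a fragment: a set of query atoms plus structure."""

    atoms: frozenset[int]
    mol: Chem.Mol
    key: str
    plain: str
    depth: int
    resolved_as: str | None = None
    dead_end: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def resolved(self) -> bool:
        return self.resolved_as is not None


@dataclass(frozen=True)
class DigestionEvent:
    parent: frozenset[int]
    unit_id: str
    cut_bonds: tuple[tuple[int, int], ...]  # original-atom index pairs
    children: tuple[frozenset[int], ...]


def prepare_target(target: Chem.Mol) -> Chem.Mol:
    """Copy of *target* whose atoms remember their original index."""
    mol = Chem.Mol(target)
    for atom in mol.GetAtoms():
        atom.SetIntProp(ORIG_IDX_PROP, atom.GetIdx())
    return mol


def _orig_indices(mol: Chem.Mol) -> list[int]:
    return [a.GetIntProp(ORIG_IDX_PROP) for a in mol.GetAtoms()]


def _clear_dangling_bond_stereo(rw: Chem.RWMol) -> None:
    """Drop E/Z descriptors whose reference atoms are no longer neighbours."""
    for bond in rw.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREONONE:
            continue
        begin, end = bond.GetBeginAtom(), bond.GetEndAtom()
        neighbours = {a.GetIdx() for a in begin.GetNeighbors()} | {
            a.GetIdx() for a in end.GetNeighbors()
        }
        if any(idx not in neighbours for idx in bond.GetStereoAtoms()):
            bond.SetStereo(Chem.BondStereo.STEREONONE)


def digest(parent: Fragment, emb: Embedding) -> list[Fragment]:
    """Cut every boundary bond of *emb* inside *parent*.

    Returns the child fragments (attachment-flagged at cut positions),
    or ``[parent]`` unchanged when the embedding spans the whole
    fragment.  Stereo descriptors that referenced a cut bond are
    dropped.  Raises :class:`ContractViolation` if the embedding maps
    outside the fragment and ``ValueError`` if a cut produces fragments
    that cannot be sanitized (e.g. a sliced aromatic ring).
    """
    n = parent.mol.GetNumAtoms()
    embedded = set(emb.atom_map)
    if any(i < 0 or i >= n for i in embedded):
        raise ContractViolation("embedding atoms outside parent fragment")
    boundary = [
        b
        for b in parent.mol.GetBonds()
        if (b.GetBeginAtomIdx() in embedded) != (b.GetEndAtomIdx() in embedded)
    ]
    if not boundary:
        return [parent]
    rw = Chem.RWMol(parent.mol)
    cut_orig: list[tuple[int, int]] = []
    for bond in boundary:
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        oi = rw.GetAtomWithIdx(i).GetIntProp(ORIG_IDX_PROP)
        oj = rw.GetAtomWithIdx(j).GetIntProp(ORIG_IDX_PROP)
        cut_orig.append((min(oi, oj), max(oi, oj)))
        rw.RemoveBond(i, j)
        mark_attachment(rw.GetAtomWithIdx(i))
        mark_attachment(rw.GetAtomWithIdx(j))
    _clear_dangling_bond_stereo(rw)
    from rdkit import rdBase

    with rdBase.BlockLogs():
        pieces = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=True)
    children: list[Fragment] = []
    for piece in pieces:
        Chem.AssignStereochemistry(piece, cleanIt=True, force=True)
        children.append(
            Fragment(
                atoms=frozenset(_orig_indices(piece)),
                mol=piece,
                key=canonical_key(piece),
                plain=plain_key(piece),
                depth=parent.depth + 1,
            )
        )
    union = frozenset().union(*(c.atoms for c in children))
    if union != parent.atoms or sum(c.n_atoms for c in children) != parent.n_atoms:
        raise ContractViolation("digestion does not partition parent atoms")
    return children


class FragmentNetwork:
    """Directed parent -> child graph of digestion events."""

    def __init__(self, target: Chem.Mol):
        self.target = prepare_target(target)
        root_mol = Chem.Mol(self.target)
        self.root: frozenset[int] = frozenset(range(root_mol.GetNumAtoms()))
        self.fragments: dict[frozenset[int], Fragment] = {}
        self.events: list[DigestionEvent] = []
        self.children_of: dict[frozenset[int], list[int]] = {}
        self._event_keys: set = set()
        self.stage_a_non_pbu_used = 0
        self._add_fragment(
            Fragment(
                atoms=self.root,
                mol=root_mol,
                key=canonical_key(root_mol),
                plain=plain_key(root_mol),
                depth=0,
            )
        )

    def _add_fragment(self, frag: Fragment) -> Fragment:
        existing = self.fragments.get(frag.atoms)
        if existing is not None:
            return existing
        self.fragments[frag.atoms] = frag
        return frag

    def _set(self, frag: Fragment) -> None:
        self.fragments[frag.atoms] = frag

    def add_event(self, event: DigestionEvent, children: list[Fragment]) -> bool:
        dedup_key = (event.parent, frozenset(event.children))
        if dedup_key in self._event_keys:
            return False
        self._event_keys.add(dedup_key)
        self.events.append(event)
        self.children_of.setdefault(event.parent, []).append(len(self.events) - 1)
        for child in children:
            self._add_fragment(child)
        return True

    # -- introspection -------------------------------------------------
    @property
    def root_fragment(self) -> Fragment:
        return self.fragments[self.root]

    def leaves(self) -> list[Fragment]:
        return [
            f for atoms, f in self.fragments.items() if atoms not in self.children_of
        ]

    def node_keys(self) -> set[str]:
        return {f.key for f in self.fragments.values()}

    def to_networkx(self):
        """Key-level view: identical fragments share one node."""
        import networkx as nx

        g = nx.DiGraph()
        for frag in self.fragments.values():
            g.add_node(
                frag.key,
                smiles=frag.plain,
                resolved_as=frag.resolved_as,
                n_atoms=frag.n_atoms,
            )
        for ev in self.events:
            pkey = self.fragments[ev.parent].key
            for child in ev.children:
                ckey = self.fragments[child].key
                g.add_edge(pkey, ckey, unit_id=ev.unit_id, cut_bonds=list(ev.cut_bonds))
        return g

    def export_json(self) -> dict:
        return {
            "root": self.fragments[self.root].key,
            "nodes": [
                {
                    "key": f.key,
                    "smiles": f.plain,
                    "atoms": sorted(f.atoms),
                    "resolved_as": f.resolved_as,
                    "dead_end": f.dead_end,
                }
                for f in self.fragments.values()
            ],
            "events": [
                {
                    "parent": sorted(ev.parent),
                    "unit_id": ev.unit_id,
                    "cut_bonds": [list(b) for b in ev.cut_bonds],
                    "children": [sorted(c) for c in ev.children],
                }
                for ev in self.events
            ],
        }

    def export_edges_tsv(self) -> str:
        lines = ["parent_key\tchild_key\tunit_id\tcut_bonds"]
        for ev in self.events:
            pkey = self.fragments[ev.parent].key
            cuts = ";".join(f"{i}-{j}" for i, j in ev.cut_bonds)
            for child in ev.children:
                lines.append(
                    f"{pkey}\t{self.fragments[child].key}\t{ev.unit_id}\t{cuts}"
                )
        return "\n".join(lines) + "\n"


def _resolve(frag: Fragment, key_to_units: dict[str, list]) -> Fragment:
    units = key_to_units.get(frag.plain)
    if not units:
        return frag
    best = min(units, key=lambda u: (_ROLE_ORDER[u.role], u.id))
    return replace(frag, resolved_as=best.id)


def _selected_entries(qlib: QueryLibrary):
    """PBUs first, then the largest ceil(N/2) non-preferential units."""
    budget = unit_budget(qlib.n_bul)
    pbus = [e for e in qlib if e.unit.role == "PBU"]
    others = [e for e in qlib if e.unit.role != "PBU"][:budget]
    return pbus + others, len(others)


def _embeddings_for(frag: Fragment, entry, config: DisassemblerConfig):
    if not entry.rescued:
        return find_embeddings(
            frag.mol,
            entry.unit.mol,
            max_embeddings=config.max_embeddings,
            use_chirality=config.use_chirality,
            unit_id=entry.unit.id,
        )
    # rescued units have no exact embedding; place them via relaxed MCS
    mcs = mcs_with_ambiguity(frag.mol, entry.unit.mol, timeout=config.mcs_timeout)
    if not mcs.covers_unit or not mcs.target_match:
        return []
    return [Embedding(entry.unit.id, mcs.target_match, via_mcs=True)]


def build_network(
    target: Chem.Mol,
    qlib: QueryLibrary,
    config: DisassemblerConfig = DEFAULT_CONFIG,
) -> FragmentNetwork:
    """Build the fragment network for *target* over the selected units.

    Raises :class:`SearchSpaceExceeded` when the node or depth cap is
    hit; dead-end leaves (nothing embeds) are recorded, not raised.
    """
    net = FragmentNetwork(target)
    key_to_units: dict[str, list] = {}
    for entry in qlib:
        key_to_units.setdefault(entry.unit.key, []).append(entry.unit)
    selected, _ = _selected_entries(qlib)

    net._set(_resolve(net.root_fragment, key_to_units))

    def _digest_with(frag: Fragment, entry) -> bool:
        made_event = False
        for emb in _embeddings_for(frag, entry, config):
            try:
                children = digest(frag, emb)
            except ContractViolation:
                raise
            except Exception as exc:  # unsanitizable cut (sliced ring)
                log.info("digestion by %s skipped: %s", entry.unit.id, exc)
                continue
            if len(children) == 1 and children[0].atoms == frag.atoms:
                continue
            resolved_children = []
            for child in children:
                known = net.fragments.get(child.atoms)
                resolved_children.append(
                    known if known is not None else _resolve(child, key_to_units)
                )
            event = DigestionEvent(
                parent=frag.atoms,
                unit_id=entry.unit.id,
                cut_bonds=tuple(
                    sorted(
                        {
                            b
                            for b in _cut_bonds_of(frag, emb)
                        }
                    )
                ),
                children=tuple(c.atoms for c in resolved_children),
            )
            if net.add_event(event, resolved_children):
                made_event = True
            if len(net.fragments) > config.max_network_nodes:
                raise SearchSpaceExceeded(
                    f"fragment network exceeded {config.max_network_nodes} nodes"
                )
        return made_event

    # Stage A: digest the root with every selected unit
    for entry in selected:
        if entry.unit.role != "PBU":
            net.stage_a_non_pbu_used += 1
        _digest_with(net.root_fragment, entry)

    # Stage B: digest unresolved leaves until everything resolves or stalls.
    # The unit budget restricts stage A only; leaves are digested against
    # every unit of the query-specific library (rescued ones included).
    stage_b_entries = list(qlib)
    attempted: set[tuple[frozenset[int], str]] = set()
    progress = True
    while progress:
        progress = False
        for frag in net.leaves():
            if frag.resolved or frag.dead_end or frag.atoms == net.root:
                continue
            if frag.depth >= config.max_digestion_depth:
                raise SearchSpaceExceeded(
                    f"digestion depth exceeded {config.max_digestion_depth}"
                )
            any_event = False
            for entry in stage_b_entries:
                if (frag.atoms, entry.unit.id) in attempted:
                    continue
                attempted.add((frag.atoms, entry.unit.id))
                if _digest_with(frag, entry):
                    any_event = True
            if any_event:
                progress = True
            elif frag.atoms not in net.children_of:
                net._set(replace(frag, dead_end=True))
    return net


def _cut_bonds_of(frag: Fragment, emb: Embedding) -> list[tuple[int, int]]:
    embedded = set(emb.atom_map)
    out = []
    for b in frag.mol.GetBonds():
        if (b.GetBeginAtomIdx() in embedded) != (b.GetEndAtomIdx() in embedded):
            oi = b.GetBeginAtom().GetIntProp(ORIG_IDX_PROP)
            oj = b.GetEndAtom().GetIntProp(ORIG_IDX_PROP)
            out.append((min(oi, oj), max(oi, oj)))
    return out
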