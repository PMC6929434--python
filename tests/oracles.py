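"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they verify: the bond-subset
oracle enumerates every combination of cuttable bonds exhaustively, and
the subgraph-isomorphism oracle matches on a NetworkX graph built
directly from atoms and bonds, bypassing RDKit's substructure engine.
"""
from itertools import combinations

import networkx as nx
from rdkit import Chem

from biounits.chemgraph import plain_key


def cuttable_bonds(mol):
    """Acyclic single non-aromatic bonds between heavy atoms."""
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.GetIsAromatic()
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]


def fragments_for_cut(mol, bond_indices):
    rw = Chem.RWMol(mol)
    for idx in bond_indices:
        bond = mol.GetBondWithIdx(idx)
        rw.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    try:
        return list(Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=True))
    except Exception:
        return None


def brute_force_candidates(mol, unit_keys):
    """Every bond subset whose fragments all equal library units.

    Returns combinations as (sorted plain-key tuple, largest fragment
    atoms, fragment count), deduplicated and ranked by the two sort
    keys with the structural tie-break.
    """
    bonds = cuttable_bonds(mol)
    seen = {}
    for r in range(len(bonds) + 1):
        for subset in combinations(bonds, r):
            frags = fragments_for_cut(mol, subset)
            if frags is None:
                continue
            keys = tuple(sorted(plain_key(f) for f in frags))
            if any(k not in unit_keys for k in keys):
                continue
            largest = max(f.GetNumHeavyAtoms() for f in frags)
            seen.setdefault(keys, (largest, len(frags)))
    ranked = sorted(
        ((keys, largest, n) for keys, (largest, n) in seen.items()),
        key=lambda t: (-t[1], t[2], t[0]),
    )
    return ranked


def mol_to_graph(mol):
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            aromatic=atom.GetIsAromatic(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=str(bond.GetBondType()),
        )
    return g


def subgraph_embeds(target, unit):
    """Element- and bond-order-exact subgraph isomorphism, via NetworkX.

    Bond kinds are compared strictly (aromatic is distinct from double);
    atom aromaticity flags are not compared, mirroring the matching
    contract (a methyl query atom may map onto a ring carbon when the
    connecting bond is single).
    """
    gm = nx.algorithms.isomorphism.GraphMatcher(
        mol_to_graph(target),
        mol_to_graph(unit),
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    return gm.subgraph_is_monomorphic()


def count_embeddings(target, unit):
    gm = nx.algorithms.isomorphism.GraphMatcher(
        mol_to_graph(target),
        mol_to_graph(unit),
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    return len({frozenset(m) for m in gm.subgraph_monomorphisms_iter()})
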