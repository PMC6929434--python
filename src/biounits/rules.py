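"""Chemical transformation rules used to derive unit variants.

Basic units (BBUs) are curated biosynthetic intermediates; derivative
units (DBUs) are generated from them by applying simple chemical
transformations that mimic the tailoring reactions commonly seen between
a starting material and the residue it leaves in a natural product:
loss of small groups (hydroxyl, carboxyl, amino, carbonyl, phosphate),
redox interconversions (amine <-> ketone, single <-> double bond),
cleavage of activating groups (thioester/CoA, nucleotide), hydrolysis of
esters and amides, and opening/closing of medium-sized rings.

Most rules are declarative reaction SMARTS; ring opening and closing are
explicit graph edits bounded to rings of size 5-7.  Each rule applied to
a structure yields one product per distinct matching site, deduplicated
by canonical key.  Denitration is shipped disabled by default.
"""
from __future__ import annotations

import contextlib
from dataclasses import dataclass, field

from rdkit import Chem, rdBase
from rdkit.Chem import AllChem

from .chemgraph import canonical_key

RING_SIZES = (5, 6, 7)


@dataclass(frozen=True)
class TransformationRule:
    """One named structural rewrite.

    ``kind`` selects the engine: ``reaction`` rules carry one or more
    reaction SMARTS; ``ring_open``/``ring_close`` are graph edits.  When
    ``keep_mapped_only`` is set, only the product component containing
    mapped reactant atoms is kept (truncation rules such as CoA removal
    keep the acyl side, not the leaving group).
    """

    name: str
    kind: str = "reaction"
    smarts: tuple[str, ...] = field(default=())
    keep_mapped_only: bool = False
    enabled: bool = True


RULES: tuple[TransformationRule, ...] = (
    TransformationRule("dehydroxylation", smarts=("[#6:1][OX2H1]>>[#6:1]",)),
    TransformationRule(
        "decarboxylation", smarts=("[*:1][CX3](=[OX1])[OX2H1]>>[*:1]",)
    ),
    TransformationRule("deamination", smarts=("[#6:1][NX3H2]>>[#6:1]",)),
    TransformationRule("decarbonylation", smarts=("[*:1][CX3H1]=[OX1]>>[*:1]",)),
    TransformationRule(
        "oxidative-deamination", smarts=("[CX4;H1,H2:1][NX3H2]>>[C:1]=[O]",)
    ),
    TransformationRule("amino-transfer", smarts=("[CX3:1]=[OX1]>>[C:1][N]",)),
    # "denitration": removal of a nitro/nitrate moiety; off by default
    TransformationRule(
        "denitration",
        smarts=(
            "[#6:1][N+](=[OX1])[O-]>>[#6:1]",
            "[#6:1][NX3](=[OX1])=[OX1]>>[#6:1]",
        ),
        enabled=False,
    ),
    TransformationRule(
        "dephosphorylation",
        smarts=("[*:1][OX2]P(=[OX1])([OX2H])[OX2H]>>[*:1][OX2H]",),
    ),
    TransformationRule(
        "dihydrogenation",
        smarts=(
            "[C:1]=[C:2]>>[C:1][C:2]",
            "[CX4!H0:1][CX4!H0:2]>>[C:1]=[C:2]",
        ),
    ),
    TransformationRule(
        "de-CoA",
        smarts=("[CX3:1](=[OX1:2])[SX2][#6]>>[C:1](=[O:2])[OX2H]",),
        keep_mapped_only=True,
    ),
    TransformationRule(
        "denucleotidylation",
        smarts=("[#6:1][OX2:2][P]>>[#6:1][OX2H:2]",),
        keep_mapped_only=True,
    ),
    TransformationRule("ring-opening", kind="ring_open"),
    TransformationRule("ring-closure", kind="ring_close"),
    TransformationRule(
        "hydrolysis",
        smarts=(
            "[CX3:1](=[OX1:2])[OX2:3][#6:4]>>[C:1](=[O:2])[OX2H:3].[#6:4][OX2H]",
            "[CX3:1](=[OX1:2])[NX3:3][#6:4]>>[C:1](=[O:2])[OX2H].[NX3:3][#6:4]",
        ),
    ),
)

RULES_BY_NAME = {r.name: r for r in RULES}


def default_rules(enable_denitration: bool = False) -> list[TransformationRule]:
    out = []
    for r in RULES:
        if r.name == "denitration" and not enable_denitration and not r.enabled:
            continue
        out.append(r)
    return out


def _sanitized(mol: Chem.Mol) -> Chem.Mol | None:
    # rule products routinely violate valence; that is a filter, not an error
    with contextlib.suppress(Exception), rdBase.BlockLogs():
        Chem.SanitizeMol(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        return mol
    return None


def _split_components(mol: Chem.Mol, min_atoms: int = 2) -> list[Chem.Mol]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return [mol]
    return [f for f in frags if f.GetNumHeavyAtoms() >= min_atoms]


def _mapped_component(product: Chem.Mol) -> Chem.Mol | None:
    """Connected component of a reaction product containing mapped atoms."""
    frag_ids = Chem.GetMolFrags(product)
    frags = Chem.GetMolFrags(product, asMols=True, sanitizeFrags=False)
    for ids, frag in zip(frag_ids, frags):
        if any(product.GetAtomWithIdx(i).HasProp("old_mapno") for i in ids):
            return frag
    return frags[0] if frags else None


def _run_reaction_rule(mol: Chem.Mol, rule: TransformationRule) -> list[Chem.Mol]:
    products: list[Chem.Mol] = []
    for smarts in rule.smarts:
        rxn = AllChem.ReactionFromSmarts(smarts)
        for prod_set in rxn.RunReactants((mol,)):
            for prod in prod_set:
                if rule.keep_mapped_only and len(Chem.GetMolFrags(prod)) > 1:
                    prod = _mapped_component(prod)
                    if prod is None:
                        continue
                prod = _sanitized(prod)
                if prod is None:
                    continue
                products.extend(_split_components(prod))
    return products


def _ring_open(mol: Chem.Mol) -> list[Chem.Mol]:
    ri = mol.GetRingInfo()
    products = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.GetIsAromatic():
            continue
        if not bond.IsInRing():
            continue
        if not any(ri.IsBondInRingOfSize(bond.GetIdx(), s) for s in RING_SIZES):
            continue
        rw = Chem.RWMol(mol)
        rw.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        prod = _sanitized(rw.GetMol())
        if prod is not None:
            products.append(prod)
    return products


def _free_valence(atom: Chem.Atom) -> int:
    return atom.GetTotalNumHs()


def _ring_close(mol: Chem.Mol) -> list[Chem.Mol]:
    from rdkit.Chem import rdmolops

    dmat = rdmolops.GetDistanceMatrix(mol)
    products = []
    n = mol.GetNumAtoms()
    for i in range(n):
        ai = mol.GetAtomWithIdx(i)
        if ai.GetIsAromatic() or _free_valence(ai) < 1:
            continue
        for j in range(i + 1, n):
            aj = mol.GetAtomWithIdx(j)
            if aj.GetIsAromatic() or _free_valence(aj) < 1:
                continue
            # a new i-j single bond closes a ring of size dist+1
            if int(dmat[i, j]) + 1 not in RING_SIZES:
                continue
            rw = Chem.RWMol(mol)
            rw.AddBond(i, j, Chem.BondType.SINGLE)
            prod = _sanitized(rw.GetMol())
            if prod is not None:
                products.append(prod)
    return products


def apply_rule(mol: Chem.Mol, rule: TransformationRule) -> list[Chem.Mol]:
    """All distinct products of applying *rule* once to *mol*.

    One product per matching site; site-symmetric duplicates are removed
    by canonical key; products that fall apart are split into connected
    components and components with fewer than 2 heavy atoms arising from
    such splits are dropped.  An absent pattern yields an empty list.
    """
    if rule.kind == "ring_open":
        raw = _ring_open(mol)
    elif rule.kind == "ring_close":
        raw = _ring_close(mol)
    else:
        raw = _run_reaction_rule(mol, rule)
    seen: dict[str, Chem.Mol] = {}
    for prod in raw:
        if prod.GetNumHeavyAtoms() == 0:
            continue
        seen.setdefault(canonical_key(prod), prod)
    return list(seen.values())
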