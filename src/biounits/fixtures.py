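"""Synthetic targets with planted, known unit decompositions.

The generator joins copies of library units by new acyclic single bonds
at atoms with free valence and records both the ground-truth unit
multiset and the junction bonds, so that cutting exactly those bonds
provably reproduces the planted units.  This emulates the one property
the disassembler relies on -- natural products are unit assemblies
joined by digestible bonds -- while making no attempt to emulate real
biosynthetic bond chemistry (amide condensation, glycosylation
regiochemistry, ring fusion).

The shipped suite spans single-unit identities, linear chains of 2-6
units, glycosides exercising the preferential sugar units, an
aromatic-rich target that triggers the MCS rescue, a symmetric target
with multiple embeddings of one unit, and a fatty-acid-like chain whose
correct answer exceeds the default fragment limit.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from rdkit import Chem

from .chemgraph import plain_key
from .errors import BiounitsError
from .library import BioUnit, UnitLibrary, unit_from_smiles


class PlantingError(BiounitsError):
    """Topology invalid or a junction would violate valence."""


@dataclass(frozen=True)
class PlantedMolecule:
    name: str
    mol: Chem.Mol
    units: tuple[BioUnit, ...]  # one entry per planted copy (multiset)
    junction_bonds: tuple[tuple[int, int], ...]  # assembled-molecule atom pairs
    extra_units: tuple[BioUnit, ...] = ()  # library distractors, not ground truth
    seed: int = 0

    @property
    def ground_truth_ids(self) -> tuple[str, ...]:
        return tuple(sorted(u.id for u in self.units))

    @property
    def ground_truth_keys(self) -> tuple[str, ...]:
        return tuple(sorted(u.key for u in self.units))

    @property
    def n_units(self) -> int:
        return len(self.units)

    def library(self) -> UnitLibrary:
        """Unit library for this fixture (planted units + distractors)."""
        lib = UnitLibrary()
        for u in self.units + self.extra_units:
            lib.add(u)
        return lib

    def cut_junctions(self) -> tuple[str, ...]:
        """Plain keys of the fragments obtained by cutting the junctions."""
        rw = Chem.RWMol(self.mol)
        for i, j in self.junction_bonds:
            rw.RemoveBond(i, j)
        frags = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=True)
        return tuple(sorted(plain_key(f) for f in frags))


def _connected_tree(n_units: int, topology) -> bool:
    if n_units == 1:
        return len(topology) == 0
    if len(topology) != n_units - 1:
        return False
    parent = list(range(n_units))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ui, _, uj, _ in topology:
        ri, rj = find(ui), find(uj)
        if ri == rj:
            return False
        parent[ri] = rj
    return len({find(i) for i in range(n_units)}) == 1


def plant(
    units: list[BioUnit],
    topology: list[tuple[int, int, int, int]],
    seed: int = 0,
    name: str = "planted",
) -> PlantedMolecule:
    """Join unit copies into one molecule.

    *topology* lists junctions as ``(unit_i, atom_i, unit_j, atom_j)``;
    the junction graph over units must be a tree, and each named atom
    must have enough free valence (implicit hydrogens) for its
    junctions.
    """
    if not units:
        raise PlantingError("no units to plant")
    if not _connected_tree(len(units), topology):
        raise PlantingError("topology must form a connected acyclic junction graph")
    offsets = []
    combined = None
    for u in units:
        offsets.append(0 if combined is None else combined.GetNumAtoms())
        combined = u.mol if combined is None else Chem.CombineMols(combined, u.mol)
    usage: dict[tuple[int, int], int] = {}
    for ui, ai, uj, aj in topology:
        usage[(ui, ai)] = usage.get((ui, ai), 0) + 1
        usage[(uj, aj)] = usage.get((uj, aj), 0) + 1
    for (ui, ai), count in usage.items():
        atom = units[ui].mol.GetAtomWithIdx(ai)
        if atom.GetTotalNumHs() < count:
            raise PlantingError(
                f"atom {ai} of unit {units[ui].id!r} lacks free valence "
                f"for {count} junction(s)"
            )
    rw = Chem.RWMol(combined)
    junctions = []
    for ui, ai, uj, aj in topology:
        i, j = offsets[ui] + ai, offsets[uj] + aj
        rw.AddBond(i, j, Chem.BondType.SINGLE)
        junctions.append((i, j))
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise PlantingError(f"junction violates valence: {exc}") from exc
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    mol.SetProp("_Name", name)
    return PlantedMolecule(
        name=name,
        mol=mol,
        units=tuple(units),
        junction_bonds=tuple(junctions),
        seed=seed,
    )


def _match_idx(mol: Chem.Mol, smarts: str, pos: int = 0) -> int:
    """Index of the *pos*-th atom of the first SMARTS match."""
    match = mol.GetSubstructMatch(Chem.MolFromSmarts(smarts))
    if not match:
        raise PlantingError(f"pattern {smarts!r} not found")
    return match[pos]


def anomeric_hydroxyl_oxygen(sugar: Chem.Mol) -> int:
    """The OH oxygen on the carbon flanked by the ring oxygen."""
    return _match_idx(sugar, "[C;R]([OX2;R])[OX2H]", 2)


def _seed_unit(uid: str) -> BioUnit:
    from .library import default_pbus, default_seed_units

    for u in default_seed_units() + default_pbus():
        if u.id == uid:
            return u
    raise KeyError(uid)


def fixture_suite() -> list[PlantedMolecule]:
    """The standard test suite of planted molecules (>= 12 fixtures)."""
    acetic = _seed_unit("acetate-C2")
    alanine = _seed_unit("L-alanine")
    trp = _seed_unit("L-tryptophan")
    lysine = _seed_unit("L-lysine")
    cadaverine = _seed_unit("cadaverine")
    cinnamate = _seed_unit("cinnamate")
    glucose = _seed_unit("alpha-D-glucose")
    rhamnose = _seed_unit("alpha-L-rhamnose")
    shikimate = _seed_unit("shikimate")
    phe = _seed_unit("L-phenylalanine")
    ethane = unit_from_smiles("ethane-C2", "CC", "BBU")
    benzene = unit_from_smiles("benzene", "c1ccccc1", "BBU")
    anthracene = unit_from_smiles("anthracene", "c1ccc2cc3ccccc3cc2c1", "BBU")
    # the anthracene-diene drawn with localized double bonds: only an
    # aromatic-rescue (relaxed-order MCS) can place it in the target
    diene = unit_from_smiles(
        "butadienyl-anthracene", r"C(=C\c1ccc2cc3ccccc3cc2c1)/C=C", "BBU"
    )
    beta_glucose = unit_from_smiles(
        "beta-D-glucose", "C([C@@H]1[C@H]([C@@H]([C@H]([C@@H](O1)O)O)O)O)O", "PBU"
    )

    glc_o = anomeric_hydroxyl_oxygen(glucose.mol)
    rha_o = anomeric_hydroxyl_oxygen(rhamnose.mol)
    aryl_ch = _match_idx(cinnamate.mol, "[cH]")

    fixtures = [
        plant([phe], [], name="phe-identity"),
        plant([shikimate], [], name="shikimate-identity"),
        plant([acetic, alanine], [(0, 0, 1, 0)], name="c2-ala"),
        plant([trp, acetic], [(0, 0, 1, 0)], name="trp-c2"),
        plant(
            [acetic, acetic, acetic],
            [(0, 0, 1, 0), (1, 0, 2, 0)],
            name="c2-chain-3",
        ),
        plant(
            [alanine, acetic, acetic, alanine],
            [(0, 0, 1, 0), (1, 0, 2, 0), (2, 0, 3, 0)],
            name="four-chain",
        ),
        plant(
            [acetic, ethane, ethane, ethane, ethane, ethane],
            [
                (0, 0, 1, 0),
                (1, 1, 2, 0),
                (2, 1, 3, 0),
                (3, 1, 4, 0),
                (4, 1, 5, 0),
            ],
            name="dodecanoic-c2",
        ),
        plant([benzene, benzene], [(0, 0, 1, 0)], name="biphenyl"),
        replace(
            plant([anthracene, benzene], [(0, 0, 1, 0)], name="phenylanthracene"),
            extra_units=(diene,),
        ),
        replace(
            plant(
                [glucose, cinnamate],
                [(0, glc_o, 1, aryl_ch)],
                name="cinnamyl-glucoside",
            ),
            extra_units=(beta_glucose,),
        ),
        plant(
            [rhamnose, cinnamate],
            [(0, rha_o, 1, _match_idx(cinnamate.mol, "[cH]"))],
            name="cinnamyl-rhamnoside",
        ),
        plant(
            [acetic, ethane, ethane, ethane],
            [(0, 0, 1, 0), (0, 0, 2, 0), (0, 0, 3, 0)],
            name="star-ethane",
        ),
        plant([lysine, alanine], [(0, 0, 1, 0)], name="lys-ala"),
        plant(
            [cadaverine, acetic, acetic],
            [(0, 0, 1, 0), (0, 6, 2, 0)],
            name="cadaverine-diacetate",
        ),
    ]
    return fixtures


def fixture_by_name(name: str) -> PlantedMolecule:
    for f in fixture_suite():
        if f.name == name:
            return f
    raise KeyError(name)
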