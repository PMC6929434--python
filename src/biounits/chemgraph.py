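"""Chemical-graph I/O and interrogation.

Molecules are RDKit ``Mol`` objects throughout the package: atoms carry
aromaticity and stereo descriptors after sanitization, hydrogens are
implicit, and fragments produced by bond digestion mark their cut
positions ("attachment points") with atom-map number 1 rather than with
dummy atoms, so that a fragment still matches units that have no stubs.

Supported input formats: MDL Molfile V2000, SMILES, InChI, and compound
identifiers resolved through a local TSV lookup table (``C`` + five
digits, no network access).  Output: canonical SMILES and Molfile V2000.
"""
from __future__ import annotations

import re
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi

from .errors import KeggLookupError, ParseError, UnsupportedStructureError

RDLogger.DisableLog("rdApp.warning")

ATTACHMENT_MAP_NUM = 1

_KEGG_ID_RE = re.compile(r"^C\d{5}$")

_FORMAT_ALIASES = {
    "molfile": "molfile-v2000",
    "mol": "molfile-v2000",
    "sdf": "molfile-v2000",
    "smi": "smiles",
}


def _check_supported(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise UnsupportedStructureError(
                "structure contains an undefined R-group/dummy atom"
            )


def parse_structure(
    text: str,
    fmt: str = "smiles",
    kegg_table: dict[str, str] | None = None,
    name: str | None = None,
) -> Chem.Mol:
    """Parse *text* into a sanitized molecule with perceived aromaticity.

    Parameters
    ----------
    text:
        Structure text (SMILES/InChI/Molfile body) or a compound id.
    fmt:
        One of ``molfile-v2000``, ``smiles``, ``inchi``, ``kegg-id``.
    kegg_table:
        Local id -> SMILES mapping; required for ``kegg-id`` input.

    Raises
    ------
    ParseError
        If the text cannot be interpreted in the given format.
    UnsupportedStructureError
        If the structure contains undefined R-group atoms.
    KeggLookupError
        If a compound id is absent from the local table.
    """
    if not text or not text.strip():
        raise ParseError("empty structure text")
    fmt = _FORMAT_ALIASES.get(fmt, fmt)
    if fmt == "kegg-id":
        cid = text.strip()
        if not _KEGG_ID_RE.match(cid):
            raise ParseError(f"not a compound identifier: {cid!r}")
        if kegg_table is None or cid not in kegg_table:
            raise KeggLookupError(f"{cid} not in local compound table")
        mol = Chem.MolFromSmiles(kegg_table[cid])
        if mol is None:
            raise ParseError(f"stored structure for {cid} is unparseable")
        mol.SetProp("_Name", name or cid)
    elif fmt == "smiles":
        mol = Chem.MolFromSmiles(text)
        if mol is None:
            raise ParseError(f"unparseable SMILES: {text!r}")
    elif fmt == "inchi":
        mol = inchi.MolFromInchi(text)
        if mol is None:
            raise ParseError(f"unparseable InChI: {text!r}")
    elif fmt == "molfile-v2000":
        mol = Chem.MolFromMolBlock(text)
        if mol is None:
            raise ParseError("unparseable Molfile")
    else:
        raise ParseError(f"unknown format: {fmt!r}")
    _check_supported(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    if name:
        mol.SetProp("_Name", name)
    return mol


def write_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES."""
    return Chem.MolToSmiles(mol)


def write_molfile(mol: Chem.Mol) -> str:
    """MDL Molfile V2000 text (2D coordinates computed on the fly)."""
    m = Chem.Mol(mol)
    from rdkit.Chem import AllChem

    AllChem.Compute2DCoords(m)
    return Chem.MolToMolBlock(m, forceV3000=False)


def canonical_key(mol: Chem.Mol) -> str:
    """Permutation-invariant, stereo-sensitive identifier of a graph.

    Attachment flags participate in the key (a fragment with a stub is a
    different object from the same structure without one), so it is the
    node identity used by the fragment network.
    """
    return Chem.MolToSmiles(mol)


def plain_key(mol: Chem.Mol) -> str:
    """Canonical key with attachment flags stripped.

    This is the identity used when testing whether a fragment *is* a
    biosynthetic unit: cutting a single bond and refilling the open
    valence with hydrogen must reproduce the unit exactly.
    """
    m = Chem.Mol(mol)
    for atom in m.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(m)


def mark_attachment(atom: Chem.Atom) -> None:
    atom.SetAtomMapNum(ATTACHMENT_MAP_NUM)


def is_attachment(atom: Chem.Atom) -> bool:
    return atom.GetAtomMapNum() == ATTACHMENT_MAP_NUM


def attachment_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if is_attachment(a))


def aromatic_bond_count(mol: Chem.Mol) -> int:
    """Number of bonds flagged aromatic by the perception model."""
    return sum(1 for b in mol.GetBonds() if b.GetIsAromatic())


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen atoms (explicit hydrogens are ignored)."""
    return mol.GetNumHeavyAtoms()


def load_kegg_table(path: str | Path) -> dict[str, str]:
    """Read a local ``id<TAB>smiles`` compound table."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected id<TAB>smiles")
        table[parts[0]] = parts[1]
    return table


def default_kegg_table() -> dict[str, str]:
    """The small compound table shipped with the package."""
    from importlib.resources import files

    return load_kegg_table(str(files("biounits").joinpath("data/kegg_compounds.tsv")))
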