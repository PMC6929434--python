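"""The biosynthetic-unit library (BUL).

Three kinds of units are stored:

* **BBU** -- basic units: curated biosynthetic intermediates (amino
  acids, shikimate-pathway acids, the acetate C2 unit, diamines, ...).
* **DBU** -- derivative units: each BBU after one application of a
  transformation rule (see :mod:`biounits.rules`).
* **PBU** -- preferential units: moieties such as sugar residues that
  persist unchanged downstream of their attachment and are matched with
  priority to prune the search (five monosaccharides, a shikimate and a
  betalamate moiety by default).

The library is deduplicated by stereo-aware canonical key with
precedence PBU > BBU > DBU, so its size can be smaller than the sum of
seeds and rule products.  Persistence is a plain TSV
(``id  role  smiles  seed_id  rules``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem

from .chemgraph import canonical_key, heavy_atom_count, parse_structure
from .errors import ConfigurationError, LibraryFormatError
from .rules import TransformationRule, apply_rule, default_rules

ROLES = ("PBU", "BBU", "DBU")
_ROLE_PRECEDENCE = {role: i for i, role in enumerate(ROLES)}


@dataclass(frozen=True)
class BioUnit:
    """One biosynthetic unit with its provenance."""

    id: str
    mol: Chem.Mol
    role: str
    seed_id: str | None = None
    rules: tuple[str, ...] = ()
    key: str = field(default="")
    n_atoms: int = field(default=0)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "DBU" and not self.rules:
            raise ValueError("a derivative unit must record >=1 rule")
        if self.role in ("BBU", "PBU") and self.rules:
            raise ValueError(f"a {self.role} must not carry rule provenance")
        if not self.key:
            object.__setattr__(self, "key", canonical_key(self.mol))
        if not self.n_atoms:
            object.__setattr__(self, "n_atoms", heavy_atom_count(self.mol))

    @property
    def smiles(self) -> str:
        return self.key


def unit_from_smiles(
    uid: str,
    smiles: str,
    role: str = "BBU",
    seed_id: str | None = None,
    rules: tuple[str, ...] = (),
) -> BioUnit:
    return BioUnit(uid, parse_structure(smiles, "smiles", name=uid), role, seed_id, rules)


class UnitLibrary:
    """Deduplicated, ordered container of units (PBUs iterate first)."""

    def __init__(self, units: Iterable[BioUnit] = ()):
        self._units: list[BioUnit] = []
        self._index: dict[str, str] = {}
        self._by_id: dict[str, BioUnit] = {}
        for u in units:
            self.add(u)

    def add(self, unit: BioUnit) -> bool:
        """Insert *unit* unless an equal-or-higher-precedence duplicate exists."""
        existing_id = self._index.get(unit.key)
        if existing_id is not None:
            existing = self._by_id[existing_id]
            if _ROLE_PRECEDENCE[unit.role] >= _ROLE_PRECEDENCE[existing.role]:
                return False
            self._units.remove(existing)
            del self._by_id[existing_id]
        if unit.id in self._by_id:
            raise LibraryFormatError(f"duplicate unit id {unit.id!r}")
        self._units.append(unit)
        self._index[unit.key] = unit.id
        self._by_id[unit.id] = unit
        return True

    def __iter__(self) -> Iterator[BioUnit]:
        yield from sorted(
            self._units, key=lambda u: (_ROLE_PRECEDENCE[u.role], u.id)
        )

    def __len__(self) -> int:
        return len(self._units)

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def get(self, uid: str) -> BioUnit:
        return self._by_id[uid]

    def lookup_key(self, key: str) -> BioUnit | None:
        uid = self._index.get(key)
        return self._by_id[uid] if uid else None

    @property
    def pbus(self) -> list[BioUnit]:
        return [u for u in self if u.role == "PBU"]


def _seed_rows() -> list[tuple[str, str, str]]:
    from importlib.resources import files

    rows = []
    text = files("biounits").joinpath("data/seed_units.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows.append((parts[0], parts[1], parts[2]))
    return rows


def default_seed_units() -> list[BioUnit]:
    """The shipped basic units (BBUs)."""
    return [
        unit_from_smiles(uid, smi, role)
        for uid, role, smi in _seed_rows()
        if role == "BBU"
    ]


def default_pbus() -> list[BioUnit]:
    """The seven shipped preferential units.

    Five monosaccharide residues (glucose, galactose, rhamnose,
    glucuronate, arabinose), a shikimate moiety and a betalamate moiety.
    """
    return [
        unit_from_smiles(uid, smi, role)
        for uid, role, smi in _seed_rows()
        if role == "PBU"
    ]


def build_library(
    seeds: list[BioUnit],
    pbus: list[BioUnit] | None = None,
    rules: list[TransformationRule] | None = None,
    depth: int = 1,
    min_atoms: int = 2,
) -> UnitLibrary:
    """Assemble the full unit library from seeds.

    Rule products are generated to at most *depth* rule applications
    (default 1: rules act on BBUs only, not recursively).  Products
    smaller than *min_atoms* heavy atoms are discarded -- single atoms
    match everywhere and carry no biosynthetic meaning.
    """
    if not seeds:
        raise ConfigurationError("empty seed set")
    if rules is None:
        rules = default_rules()
    lib = UnitLibrary()
    for p in pbus or ():
        lib.add(p)
    for s in seeds:
        lib.add(s)
    frontier = list(seeds)
    for _level in range(depth):
        next_frontier: list[BioUnit] = []
        for parent in frontier:
            for rule in rules:
                for i, prod in enumerate(apply_rule(parent.mol, rule)):
                    if prod.GetNumHeavyAtoms() < min_atoms:
                        continue
                    seed_id = parent.seed_id or parent.id
                    dbu = BioUnit(
                        id=f"{seed_id}~{rule.name}~{_level}.{i}",
                        mol=prod,
                        role="DBU",
                        seed_id=seed_id,
                        rules=parent.rules + (rule.name,),
                    )
                    if lib.add(dbu):
                        next_frontier.append(dbu)
        frontier = next_frontier
    return lib


_COLUMNS = ("id", "role", "smiles", "seed_id", "rules")


def save_library(lib: UnitLibrary, path: str | Path) -> None:
    lines = ["\t".join(_COLUMNS)]
    for u in lib:
        lines.append(
            "\t".join([u.id, u.role, u.smiles, u.seed_id or "", ",".join(u.rules)])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_library(path: str | Path) -> UnitLibrary:
    """Load a TSV library; duplicate structures are dropped with a warning."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise LibraryFormatError("empty library file", line=1)
    header = lines[0].rstrip("\n").split("\t")
    if tuple(header) != _COLUMNS:
        raise LibraryFormatError(
            f"expected header {'/'.join(_COLUMNS)}, got {'/'.join(header)}", line=1
        )
    lib = UnitLibrary()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise LibraryFormatError(
                f"expected {len(_COLUMNS)} columns, found {len(parts)}", line=lineno
            )
        uid, role, smi, seed_id, rule_str = parts
        rules = tuple(r for r in rule_str.split(",") if r)
        try:
            unit = unit_from_smiles(uid, smi, role, seed_id or None, rules)
        except Exception as exc:
            raise LibraryFormatError(str(exc), line=lineno) from exc
        if not lib.add(unit):
            warnings.warn(
                f"line {lineno}: duplicate structure for {uid!r} dropped",
                stacklevel=2,
            )
    return lib


def export_sdf(lib: UnitLibrary, path: str | Path) -> None:
    """SDF export with role and provenance as molecule properties."""
    from rdkit.Chem import AllChem

    writer = Chem.SDWriter(str(path))
    for u in lib:
        m = Chem.Mol(u.mol)
        AllChem.Compute2DCoords(m)
        m.SetProp("_Name", u.id)
        m.SetProp("role", u.role)
        m.SetProp("seed_id", u.seed_id or "")
        m.SetProp("rules", ",".join(u.rules))
        writer.write(m)
    writer.close()
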