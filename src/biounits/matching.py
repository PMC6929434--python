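"""Substructure matching and the query-specific unit library.

Matching is chirality-aware and aromatic-bond-strict: a unit drawn with
localized double bonds is *not* contained in an aromatic ring, and a
unit with a specified stereocentre only matches a target atom with the
same configuration (unspecified unit stereocentres match either).

Because aromatization is common in biosynthesis, strict matching falsely
rejects units whose ring system became aromatic in the product.  For
aromatic-rich queries (>= 17 aromatic bonds by default) such units are
re-tested by a maximum-common-substructure search with bond-order
comparison relaxed; a unit is rescued when the MCS covers the whole unit
and the ratio of ambiguous bonds (aromatic on one side only) to
conjugated double bonds stays small (<= 0.2 by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chemgraph import aromatic_bond_count
from .config import DEFAULT_CONFIG, DisassemblerConfig
from .library import BioUnit, UnitLibrary

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Embedding:
    """A concrete placement of a unit inside a target."""

    unit_id: str
    atom_map: tuple[int, ...]  # unit atom index -> target atom index
    via_mcs: bool = False

    @property
    def atoms(self) -> frozenset[int]:
        return frozenset(self.atom_map)


@dataclass(frozen=True)
class McsResult:
    """Relaxed-bond-order MCS between a target and a unit."""

    smarts: str
    n_atoms: int
    n_bonds: int
    n_ambiguous_bonds: int
    n_conjugated_double_bonds: int
    covers_unit: bool
    target_match: tuple[int, ...] = ()
    timed_out: bool = False

    @property
    def ambiguity_ratio(self) -> float | None:
        """Ambiguous / conjugated-double ratio; None when undefined (0/0)."""
        if self.n_conjugated_double_bonds == 0:
            return None if self.n_ambiguous_bonds == 0 else float("inf")
        return self.n_ambiguous_bonds / self.n_conjugated_double_bonds


def has_substructure(
    target: Chem.Mol, unit: Chem.Mol, use_chirality: bool = True
) -> bool:
    """True iff *unit* embeds in *target* under strict bond-kind matching."""
    return target.HasSubstructMatch(unit, useChirality=use_chirality)


def find_embeddings(
    target: Chem.Mol,
    unit: Chem.Mol,
    max_embeddings: int = 1,
    use_chirality: bool = True,
    unit_id: str = "",
) -> list[Embedding]:
    """Up to *max_embeddings* embeddings with distinct matched-atom sets.

    ``max_embeddings=1`` reproduces first-match-only behaviour; larger
    values enumerate alternatives (useful for symmetric targets where
    the first placement blocks the correct disassembly).
    """
    if max_embeddings <= 1:
        match = target.GetSubstructMatch(unit, useChirality=use_chirality)
        return [Embedding(unit_id, tuple(match))] if match else []
    matches = target.GetSubstructMatches(
        unit,
        uniquify=True,
        useChirality=use_chirality,
        maxMatches=max(64, 4 * max_embeddings),
    )
    out: list[Embedding] = []
    seen: set[frozenset[int]] = set()
    for m in matches:
        atoms = frozenset(m)
        if atoms in seen:
            continue
        seen.add(atoms)
        out.append(Embedding(unit_id, tuple(m)))
        if len(out) >= max_embeddings:
            break
    return out


def mcs_with_ambiguity(
    target: Chem.Mol, unit: Chem.Mol, timeout: int = 10
) -> McsResult:
    """MCS with any-order bond comparison, annotated with ambiguity counts.

    An *ambiguous* bond is an MCS bond whose aromatic flag differs
    between the target and the unit side.  Conjugated double bonds are
    counted on the target side of the MCS; aromatic bonds, being
    conjugated, count toward the denominator.
    """
    res = rdFMCS.FindMCS(
        [target, unit],
        bondCompare=rdFMCS.BondCompare.CompareAny,
        timeout=timeout,
    )
    if res.numAtoms == 0:
        return McsResult("", 0, 0, 0, 0, False, timed_out=res.canceled)
    query = Chem.MolFromSmarts(res.smartsString)
    tmatch = target.GetSubstructMatch(query)
    umatch = unit.GetSubstructMatch(query)
    n_amb = n_conj = 0
    if tmatch and umatch:
        for bond in query.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            tb = target.GetBondBetweenAtoms(tmatch[i], tmatch[j])
            ub = unit.GetBondBetweenAtoms(umatch[i], umatch[j])
            if tb is None or ub is None:  # pragma: no cover - defensive
                continue
            if tb.GetIsAromatic() != ub.GetIsAromatic():
                n_amb += 1
            if tb.GetIsConjugated() and tb.GetBondType() in (
                Chem.BondType.DOUBLE,
                Chem.BondType.AROMATIC,
            ):
                n_conj += 1
    return McsResult(
        smarts=res.smartsString,
        n_atoms=res.numAtoms,
        n_bonds=res.numBonds,
        n_ambiguous_bonds=n_amb,
        n_conjugated_double_bonds=n_conj,
        covers_unit=res.numAtoms == unit.GetNumHeavyAtoms(),
        target_match=tuple(tmatch),
        timed_out=res.canceled,
    )


@dataclass(frozen=True)
class QueryUnit:
    """A library unit admitted into the query-specific library."""

    unit: BioUnit
    rescued: bool = False
    mcs: McsResult | None = None


@dataclass
class QueryLibrary:
    """Units contained in the query, largest first."""

    entries: list[QueryUnit] = field(default_factory=list)

    @property
    def n_bul(self) -> int:
        return len(self.entries)

    @property
    def units(self) -> list[BioUnit]:
        return [e.unit for e in self.entries]

    @property
    def keys(self) -> set[str]:
        return {e.unit.key for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def build_query_library(
    target: Chem.Mol,
    lib: UnitLibrary,
    config: DisassemblerConfig = DEFAULT_CONFIG,
) -> QueryLibrary:
    """Select the units contained in *target* and sort them, largest first.

    Exact (strict) containment admits a unit directly.  If the target
    carries at least ``config.aromatic_rescue_threshold`` aromatic
    bonds, every excluded unit is re-tested by relaxed-order MCS and
    admitted (rescue-flagged) when the MCS covers the unit and the
    ambiguity ratio is at most ``config.ambiguity_ratio_max`` (a 0/0
    ratio passes).
    """
    rescue_active = aromatic_bond_count(target) >= config.aromatic_rescue_threshold
    entries: list[QueryUnit] = []
    for unit in lib:
        if has_substructure(target, unit.mol, use_chirality=config.use_chirality):
            entries.append(QueryUnit(unit))
            continue
        if not rescue_active:
            continue
        mcs = mcs_with_ambiguity(target, unit.mol, timeout=config.mcs_timeout)
        if mcs.timed_out:
            log.warning("MCS timed out for unit %s; rescue skipped", unit.id)
            continue
        ratio = mcs.ambiguity_ratio
        ratio_ok = ratio is None or ratio <= config.ambiguity_ratio_max
        if mcs.covers_unit and ratio_ok:
            log.warning("unit %s rescued via MCS (ratio=%s)", unit.id, ratio)
            entries.append(QueryUnit(unit, rescued=True, mcs=mcs))
    entries.sort(key=lambda e: (-e.unit.n_atoms, e.unit.id))
    return QueryLibrary(entries)
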