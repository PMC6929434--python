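"""Genetic-algorithm baseline (not knowledge-based).

An individual is a binary vector over the digestible bonds of the query
(acyclic single non-aromatic bonds between heavy atoms by default): a 1
means "cut this bond".  Fitness of an individual is the minimum, over
the fragments its cuts produce, of the best Tanimoto similarity between
that fragment and any unit of the query-specific library, using Morgan
fingerprints (radius 2, 1024 bits).  A fitness of 1.0 means every
fragment's fingerprint coincides with some unit's fingerprint -- which
does not guarantee structural identity.

Defaults follow the published baseline: population 300, crossover
probability 0.80, mutation probability 0.005 per gene, 200 generations,
top five individuals reported.  The unspecified operators are filled in
as size-3 tournament selection with a single elite and two-point
crossover; runs are bit-reproducible under a fixed seed.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemgraph import plain_key
from .errors import ConfigurationError, ContractViolation
from .matching import QueryLibrary


@dataclass
class GAConfig:
    population: int = 300
    crossover_prob: float = 0.80
    mutation_prob: float = 0.005
    generations: int = 200
    fp_radius: int = 2
    fp_bits: int = 1024
    top_k: int = 5
    tournament_size: int = 3
    elite: int = 1
    seed: int = 0
    cut_all_bonds: bool = False  # widen the genome to every bond


@dataclass(frozen=True)
class GAIndividual:
    genome: tuple[int, ...]
    fitness: float


@dataclass(frozen=True)
class DecodedCombination:
    """Fragments produced by an individual's cuts, with exact-unit labels."""

    fragment_smiles: tuple[str, ...]
    assignments: dict[str, str] = field(default_factory=dict, compare=False)

    @property
    def key_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(self.fragment_smiles))


def tanimoto(a, b) -> float:
    """|a AND b| / |a OR b| over fingerprint bits; 0/0 is defined as 0."""
    if not isinstance(a, (list, tuple)):
        return DataStructs.TanimotoSimilarity(a, b)
    if len(a) != len(b):
        raise ContractViolation("fingerprint length mismatch")
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return inter / union if union else 0.0


def digestible_bonds(mol: Chem.Mol, cut_all: bool = False) -> list[int]:
    """Bond indices eligible for cutting (the genome's positions)."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBeginAtom().GetAtomicNum() == 1:
            continue
        if bond.GetEndAtom().GetAtomicNum() == 1:
            continue
        if cut_all or (
            bond.GetBondType() == Chem.BondType.SINGLE
            and not bond.GetIsAromatic()
            and not bond.IsInRing()
        ):
            out.append(bond.GetIdx())
    return out


def _fragments_for_cuts(mol: Chem.Mol, bond_indices: list[int]) -> list[Chem.Mol]:
    if not bond_indices:
        return [Chem.Mol(mol)]
    rw = Chem.RWMol(mol)
    pairs = [
        (mol.GetBondWithIdx(b).GetBeginAtomIdx(), mol.GetBondWithIdx(b).GetEndAtomIdx())
        for b in bond_indices
    ]
    for i, j in pairs:
        rw.RemoveBond(i, j)
    out = []
    for frag in Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=False):
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            continue
        out.append(frag)
    return out


class FitnessEvaluator:
    """Caches unit fingerprints and genome fitnesses for one query."""

    def __init__(self, target: Chem.Mol, qlib: QueryLibrary, cfg: GAConfig):
        if len(qlib) == 0:
            raise ConfigurationError("query-specific library is empty")
        self.target = target
        self.qlib = qlib
        self.cfg = cfg
        self.bonds = digestible_bonds(target, cut_all=cfg.cut_all_bonds)
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=cfg.fp_radius, fpSize=cfg.fp_bits
        )
        self._unit_fps = [self._gen.GetFingerprint(u.mol) for u in qlib.units]
        self._cache: dict[tuple[int, ...], float] = {}

    def fingerprint(self, mol: Chem.Mol):
        return self._gen.GetFingerprint(mol)

    def fragments(self, genome: tuple[int, ...]) -> list[Chem.Mol]:
        cuts = [b for bit, b in zip(genome, self.bonds) if bit]
        return _fragments_for_cuts(self.target, cuts)

    def __call__(self, genome: tuple[int, ...]) -> float:
        if len(genome) != len(self.bonds):
            raise ContractViolation("genome length != number of digestible bonds")
        cached = self._cache.get(genome)
        if cached is not None:
            return cached
        frags = self.fragments(genome)
        if not frags:
            fit = 0.0
        else:
            fit = min(
                max(
                    (tanimoto(self.fingerprint(f), ufp) for ufp in self._unit_fps),
                    default=0.0,
                )
                for f in frags
            )
        self._cache[genome] = fit
        return fit

    def decode(self, genome: tuple[int, ...]) -> DecodedCombination:
        unit_by_key = {e.unit.key: e.unit.id for e in self.qlib}
        smiles = []
        assignments = {}
        for frag in self.fragments(genome):
            smi = plain_key(frag)
            smiles.append(smi)
            if smi in unit_by_key:
                assignments[smi] = unit_by_key[smi]
        return DecodedCombination(tuple(sorted(smiles)), assignments)


def fitness(genome, target: Chem.Mol, qlib: QueryLibrary, cfg: GAConfig | None = None):
    """Convenience one-shot fitness evaluation."""
    ev = FitnessEvaluator(target, qlib, cfg or GAConfig())
    return ev(tuple(genome))


def _two_point_crossover(a, b, rng: random.Random):
    n = len(a)
    if n < 2:
        return a, b
    i, j = sorted(rng.sample(range(n + 1), 2))
    return a[:i] + b[i:j] + a[j:], b[:i] + a[i:j] + b[j:]


def _mutate(genome, prob: float, rng: random.Random):
    return tuple(1 - g if rng.random() < prob else g for g in genome)


def _tournament(pop, fits, size: int, rng: random.Random):
    best = None
    for _ in range(size):
        i = rng.randrange(len(pop))
        if best is None or fits[i] > fits[best]:
            best = i
    return pop[best]


def run_ga(
    target: Chem.Mol,
    qlib: QueryLibrary,
    cfg: GAConfig | None = None,
    log: list | None = None,
) -> list[tuple[GAIndividual, DecodedCombination]]:
    """Generational GA; returns the top-k distinct individuals at the end.

    When *log* is given, one ``(generation, best, mean)`` triple is
    appended per generation.
    """
    cfg = cfg or GAConfig()
    evaluator = FitnessEvaluator(target, qlib, cfg)
    rng = random.Random(cfg.seed)
    n_bonds = len(evaluator.bonds)
    pop = [
        tuple(1 if rng.random() < 0.5 else 0 for _ in range(n_bonds))
        for _ in range(cfg.population)
    ]
    fits = [evaluator(g) for g in pop]
    for gen in range(cfg.generations):
        order = sorted(range(len(pop)), key=lambda i: -fits[i])
        elites = [pop[i] for i in order[: cfg.elite]]
        offspring: list[tuple[int, ...]] = []
        while len(offspring) < cfg.population - len(elites):
            p1 = _tournament(pop, fits, cfg.tournament_size, rng)
            p2 = _tournament(pop, fits, cfg.tournament_size, rng)
            if rng.random() < cfg.crossover_prob:
                c1, c2 = _two_point_crossover(p1, p2, rng)
            else:
                c1, c2 = p1, p2
            offspring.append(_mutate(c1, cfg.mutation_prob, rng))
            if len(offspring) < cfg.population - len(elites):
                offspring.append(_mutate(c2, cfg.mutation_prob, rng))
        pop = elites + offspring
        fits = [evaluator(g) for g in pop]
        if log is not None:
            log.append((gen, max(fits), sum(fits) / len(fits)))
    ranked = sorted(zip(pop, fits), key=lambda t: (-t[1], t[0]))
    out: list[tuple[GAIndividual, DecodedCombination]] = []
    seen: set[tuple[int, ...]] = set()
    for genome, fit in ranked:
        if genome in seen:
            continue
        seen.add(genome)
        out.append((GAIndividual(genome, fit), evaluator.decode(genome)))
        if len(out) >= cfg.top_k:
            break
    return out
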