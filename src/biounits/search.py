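"""Candidate enumeration over the fragment network.

A *combination* is a multiset of fragments that jointly partition the
query's atoms.  Starting from the whole molecule, a queue-based breadth
first search repeatedly replaces a fragment by the children of one of
its digestion events, as long as the number of fragments stays within a
limit derived from the query's heavy-atom count N:

    limit = ceil(N / k),  k = 1 (N <= 4), 3 (5-24), 4 (25-53), 6 (N >= 54)

A combination whose fragments are all identical to library units is a
candidate.  Candidates are sorted by descending size of their largest
fragment, then by ascending fragment count, with a deterministic
structural tie-break.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .matching import QueryLibrary
    from .network import Fragment, FragmentNetwork

_ROLE_ORDER = {"PBU": 0, "BBU": 1, "DBU": 2}


def unit_budget(n_bul: int) -> int:
    """Maximum number of selected units: ceil(N/2) for a library of N."""
    if n_bul < 0:
        raise ValueError("library size must be non-negative")
    return math.ceil(n_bul / 2)


def fragment_limit(n_atoms: int) -> int:
    """Upper limit on fragments per combination, from the heavy-atom count."""
    if n_atoms < 1:
        raise ValueError("atom count must be >= 1")
    if n_atoms <= 4:
        k = 1
    elif n_atoms <= 24:
        k = 3
    elif n_atoms <= 53:
        k = 4
    else:
        k = 6
    return math.ceil(n_atoms / k)


@dataclass(frozen=True)
class Combination:
    """A multiset of fragments covering the whole query."""

    fragments: tuple["Fragment", ...]
    resolved: bool
    #: plain fragment key -> ids of all units identical to that fragment
    assignments: dict[str, tuple[str, ...]] = field(default_factory=dict, compare=False)
    #: plain fragment key -> the unit id reported for it
    reported: dict[str, str] = field(default_factory=dict, compare=False)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def largest_fragment_atoms(self) -> int:
        return max(f.n_atoms for f in self.fragments)

    @property
    def key_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(f.plain for f in self.fragments))

    def sort_key(self):
        return (-self.largest_fragment_atoms, self.n_fragments, self.key_multiset)


class CandidateList(list):
    """Combinations sorted by the two ranking keys."""


def sort_candidates(cands: list[Combination]) -> CandidateList:
    """Stable sort: largest fragment (desc), fragment count (asc), keys."""
    return CandidateList(sorted(cands, key=Combination.sort_key))


def _assign_units(comb_frags, qlib: "QueryLibrary") -> tuple[dict, dict, bool]:
    key_to_units: dict[str, list] = {}
    for entry in qlib:
        key_to_units.setdefault(entry.unit.key, []).append(entry.unit)
    assignments: dict[str, tuple[str, ...]] = {}
    reported: dict[str, str] = {}
    all_resolved = True
    for frag in comb_frags:
        units = key_to_units.get(frag.plain)
        if not units:
            all_resolved = False
            continue
        ordered = sorted(units, key=lambda u: (_ROLE_ORDER[u.role], u.id))
        assignments[frag.plain] = tuple(u.id for u in ordered)
        reported[frag.plain] = ordered[0].id
    return assignments, reported, all_resolved


def enumerate_candidates(
    net: "FragmentNetwork",
    qlib: "QueryLibrary",
    limit: int,
) -> CandidateList:
    """Queue-based enumeration of resolved combinations.

    Pops a combination, emits it if every fragment equals a unit, and
    pushes each variant in which one fragment is replaced by the
    children of one of its digestion events, subject to the fragment
    limit.  Combinations are deduplicated by their multiset of fragment
    keys.  An empty result means no disassembly was found within the
    limit -- an outcome, not an error.
    """
    if limit < 1:
        raise ValueError("fragment limit must be >= 1")
    unit_keys = qlib.keys
    root = net.root_fragment
    queue: deque[tuple["Fragment", ...]] = deque([(root,)])
    visited: set[tuple[str, ...]] = {(root.plain,)}
    emitted: set[tuple[str, ...]] = set()
    candidates: list[Combination] = []
    while queue:
        frags = queue.popleft()
        if all(f.plain in unit_keys for f in frags):
            keys = tuple(sorted(f.plain for f in frags))
            if keys not in emitted:
                emitted.add(keys)
                assignments, reported, _ = _assign_units(frags, qlib)
                candidates.append(
                    Combination(
                        fragments=frags,
                        resolved=True,
                        assignments=assignments,
                        reported=reported,
                    )
                )
        for i, frag in enumerate(frags):
            for ev_idx in net.children_of.get(frag.atoms, ()):
                event = net.events[ev_idx]
                children = [net.fragments[a] for a in event.children]
                new_frags = tuple(
                    sorted(
                        frags[:i] + tuple(children) + frags[i + 1 :],
                        key=lambda f: (-f.n_atoms, f.plain, sorted(f.atoms)),
                    )
                )
                if len(new_frags) > limit:
                    continue
                sig = tuple(sorted(f.plain for f in new_frags))
                if sig in visited:
                    continue
                visited.add(sig)
                queue.append(new_frags)
    return sort_candidates(candidates)
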