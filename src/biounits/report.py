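"""End-to-end disassembly workflow and result rendering.

``disassemble`` runs the five steps in order -- parse the query, build
the query-specific unit library, build the fragment network, enumerate
and sort candidate combinations, and assemble the report -- and returns
a :class:`DisassemblyReport`.  "No disassembly found" and "search space
exceeded" are distinct, non-crash outcomes carried in ``status``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from . import chemgraph
from .config import DEFAULT_CONFIG, DisassemblerConfig
from .errors import SearchSpaceExceeded
from .library import UnitLibrary
from .matching import QueryLibrary, build_query_library
from .network import FragmentNetwork, build_network
from .search import CandidateList, Combination, enumerate_candidates, fragment_limit

STATUS_OK = "ok"
STATUS_NO_UNITS = "no units matched"
STATUS_NO_DISASSEMBLY = "no disassembly found"
STATUS_SEARCH_EXCEEDED = "search space exceeded"

#: fixed qualitative palette (12 colours, cycled), assigned to fragments
#: in decreasing size order so reruns colour identically
PALETTE = [
    (0.65, 0.81, 0.89),
    (0.98, 0.60, 0.60),
    (0.70, 0.87, 0.54),
    (0.99, 0.75, 0.44),
    (0.79, 0.70, 0.84),
    (0.99, 0.93, 0.44),
    (0.55, 0.63, 0.80),
    (0.95, 0.61, 0.73),
    (0.60, 0.85, 0.78),
    (0.85, 0.85, 0.55),
    (0.80, 0.58, 0.46),
    (0.70, 0.70, 0.70),
]


@dataclass
class DisassemblyReport:
    query_name: str
    query_smiles: str
    status: str
    qlib: QueryLibrary
    candidates: CandidateList
    best: Combination | None
    fragment_limit: int
    config: DisassemblerConfig
    atom_colors: dict[int, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "query": {"name": self.query_name, "smiles": self.query_smiles},
            "status": self.status,
            "fragment_limit": self.fragment_limit,
            "query_library": [
                {
                    "id": e.unit.id,
                    "role": e.unit.role,
                    "n_atoms": e.unit.n_atoms,
                    "rescued": e.rescued,
                }
                for e in self.qlib
            ],
            "candidates": [
                {
                    "rank": rank + 1,
                    "n_fragments": c.n_fragments,
                    "largest_fragment_atoms": c.largest_fragment_atoms,
                    "fragments": [
                        {
                            "smiles": f.plain,
                            "atoms": sorted(f.atoms),
                            "unit": c.reported.get(f.plain),
                            "all_units": list(c.assignments.get(f.plain, ())),
                        }
                        for f in c.fragments
                    ],
                }
                for rank, c in enumerate(self.candidates)
            ],
            "atom_colors": {str(k): v for k, v in sorted(self.atom_colors.items())},
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def candidates_tsv(self) -> str:
        lines = ["rank\tn_fragments\tlargest_fragment_atoms\tfragments\tunits"]
        for rank, c in enumerate(self.candidates, start=1):
            frags = ";".join(f.plain for f in c.fragments)
            units = ";".join(c.reported.get(f.plain, "") for f in c.fragments)
            lines.append(
                f"{rank}\t{c.n_fragments}\t{c.largest_fragment_atoms}\t{frags}\t{units}"
            )
        return "\n".join(lines) + "\n"


def _color_assignment(best: Combination) -> dict[int, int]:
    colors: dict[int, int] = {}
    ordered = sorted(best.fragments, key=lambda f: (-f.n_atoms, f.plain, sorted(f.atoms)))
    for color_idx, frag in enumerate(ordered):
        for atom in frag.atoms:
            colors[atom] = color_idx
    return colors


def disassemble(
    text: str,
    fmt: str = "smiles",
    library: UnitLibrary | None = None,
    config: DisassemblerConfig = DEFAULT_CONFIG,
    kegg_table: dict[str, str] | None = None,
    name: str | None = None,
) -> DisassemblyReport:
    """Run the full workflow on one query molecule."""
    if library is None:
        from .library import build_library, default_pbus, default_seed_units

        library = build_library(default_seed_units(), default_pbus())
    target = chemgraph.parse_structure(text, fmt, kegg_table=kegg_table, name=name)
    qname = name or (target.GetProp("_Name") if target.HasProp("_Name") else "query")
    limit = config.fragment_limit_override or fragment_limit(
        chemgraph.heavy_atom_count(target)
    )
    qlib = build_query_library(target, library, config)
    meta = {
        "n_library_units": len(library),
        "n_query_units": qlib.n_bul,
        "n_rescued": sum(1 for e in qlib if e.rescued),
        "aromatic_bonds": chemgraph.aromatic_bond_count(target),
        "config": {
            "aromatic_rescue_threshold": config.aromatic_rescue_threshold,
            "ambiguity_ratio_max": config.ambiguity_ratio_max,
            "max_embeddings": config.max_embeddings,
        },
    }
    if qlib.n_bul == 0:
        return DisassemblyReport(
            qname, chemgraph.write_smiles(target), STATUS_NO_UNITS, qlib,
            CandidateList(), None, limit, config, metadata=meta,
        )
    try:
        net = build_network(target, qlib, config)
    except SearchSpaceExceeded as exc:
        meta["cap"] = str(exc)
        return DisassemblyReport(
            qname, chemgraph.write_smiles(target), STATUS_SEARCH_EXCEEDED, qlib,
            CandidateList(), None, limit, config, metadata=meta,
        )
    meta["n_network_nodes"] = len(net.fragments)
    meta["n_digestion_events"] = len(net.events)
    meta["stage_a_non_pbu_used"] = net.stage_a_non_pbu_used
    candidates = enumerate_candidates(net, qlib, limit)
    if not candidates:
        return DisassemblyReport(
            qname, chemgraph.write_smiles(target), STATUS_NO_DISASSEMBLY, qlib,
            CandidateList(), None, limit, config, metadata=meta,
        )
    best = candidates[0]
    return DisassemblyReport(
        qname,
        chemgraph.write_smiles(target),
        STATUS_OK,
        qlib,
        candidates,
        best,
        limit,
        config,
        atom_colors=_color_assignment(best),
        metadata=meta,
    )


def render_svg(target: Chem.Mol, combination: Combination, legend: str = "") -> str:
    """2D depiction with atoms/bonds coloured by fragment membership.

    Bonds joining different fragments stay unhighlighted; fragments are
    coloured in decreasing size order from a fixed palette.
    """
    mol = Chem.Mol(target)
    Chem.rdDepictor.Compute2DCoords(mol)
    colors = _color_assignment(combination)
    atom_cols = {i: PALETTE[c % len(PALETTE)] for i, c in colors.items()}
    bond_cols = {}
    highlight_bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in colors and j in colors and colors[i] == colors[j]:
            highlight_bonds.append(bond.GetIdx())
            bond_cols[bond.GetIdx()] = PALETTE[colors[i] % len(PALETTE)]
    if not legend:
        parts = []
        for frag in sorted(
            combination.fragments, key=lambda f: (-f.n_atoms, f.plain)
        ):
            unit = combination.reported.get(frag.plain, "?")
            parts.append(unit)
        legend = " + ".join(parts)
    drawer = rdMolDraw2D.MolDraw2DSVG(640, 480)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        mol,
        highlightAtoms=list(atom_cols),
        highlightAtomColors=atom_cols,
        highlightBonds=highlight_bonds,
        highlightBondColors=bond_cols,
        legend=legend,
    )
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


def write_outputs(
    report: DisassemblyReport,
    out_dir: str | Path,
    target: Chem.Mol | None = None,
    network: FragmentNetwork | None = None,
) -> None:
    """Write report.json, candidates.tsv, result.svg and network.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    (out / "candidates.tsv").write_text(report.candidates_tsv())
    if report.best is not None and target is not None:
        (out / "result.svg").write_text(render_svg(target, report.best))
    if network is not None:
        (out / "network.json").write_text(json.dumps(network.export_json(), indent=2))
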