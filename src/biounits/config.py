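"""Run-time configuration.

Every threshold of the disassembly workflow lives here with its default:
the aromatic-bond count that triggers the MCS rescue (17), the maximum
ratio of ambiguous to conjugated double bonds for a rescue (0.2), the
number of substructure embeddings explored per unit (1, i.e. only the
first match found), and the hard caps that make runaway searches fail
loudly instead of hanging.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class DisassemblerConfig:
    #: number of aromatic bonds in the query at or above which excluded
    #: units are re-tested by relaxed-bond-order MCS
    aromatic_rescue_threshold: int = 17
    #: a unit is rescued only if ambiguous bonds / conjugated double bonds <= this
    ambiguity_ratio_max: float = 0.2
    #: embeddings explored per (fragment, unit) pair; 1 = first match only,
    #: larger values enumerate distinct matched-atom sets
    max_embeddings: int = 1
    #: seconds allowed per MCS call before the rescue is skipped for that unit
    mcs_timeout: int = 10
    #: hard caps on fragment-network construction
    max_network_nodes: int = 10_000
    max_digestion_depth: int = 12
    #: override the atom-count-derived fragment limit (None = use the formula)
    fragment_limit_override: int | None = None
    #: treat the denitration transformation rule as enabled
    enable_denitration: bool = False
    #: substructure matching honours stereocentres specified on the unit
    use_chirality: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DisassemblerConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = DisassemblerConfig()
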