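"""Shared domain types.

Residue indices are 0-based and inclusive internally; report writers
convert to the 1-based convention used in structure files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

HELIX_CODE = "H"
COIL_CODE = "c"

#: Assigner roles in canonical order.
ASSIGNERS = ("PDB", "DSSP", "Stride")

#: Consensus modes -> required assigner roles.
CONSENSUS_MODES: Mapping[str, tuple[str, ...]] = {
    "pdb-dssp-stride": ("PDB", "DSSP", "Stride"),
    "pdb-dssp": ("PDB", "DSSP"),
    "pdb-stride": ("PDB", "Stride"),
    "dssp-stride": ("DSSP", "Stride"),
    "single": ("PDB",),
}


@dataclass
class ChainRecord:
    """One protein chain: sequence, per-assigner annotations, class label."""

    chain_id: str
    sequence: str
    annotations: dict[str, str] = field(default_factory=dict)
    class_label: str = "all-alpha"

    def __post_init__(self) -> None:
        for role, ann in self.annotations.items():
            if len(ann) != len(self.sequence):
                raise ValueError(
                    f"chain {self.chain_id}: annotation for {role!r} has length "
                    f"{len(ann)}, sequence has length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class HelixInstance:
    """A single helix occurrence; ``start``/``end`` are 0-based inclusive."""

    chain_id: str
    start: int
    end: int
    exclusive: bool = False
    consensus_mode: str = "single"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Datamart:
    """Per-length helix counts plus member instances.

    ``counts[L]`` is the number of helices of length ``L``; exclusive and
    nonexclusive sub-marts must add up to the combined mart.
    """

    name: str
    counts: dict[int, int] = field(default_factory=dict)
    members: list[HelixInstance] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def instances_of_length(self, length: int) -> list[HelixInstance]:
        return [h for h in self.members if h.length == length]
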