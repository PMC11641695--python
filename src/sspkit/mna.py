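"""Canonical multilevel atom-neighborhood descriptor strings.

A level-0 descriptor of an atom is its label: the element symbol, prefixed
with ``-`` when the atom lies on no cycle.  A level-k descriptor appends,
in parentheses, the lexicographically sorted level-(k-1) descriptors of all
bonded neighbors, concatenated without separators:

    level 0:  -O
    level 1:  -O(-H-H)
    level 2:  -H(-O(-H-H))

Only atom labels and the bond list enter the strings — bond orders and
charges are ignored.  Hydrogens are ordinary graph atoms and appear both as
centers and as neighbors.  Strings are built bottom-up per level (dynamic
programming over stored lower-level strings), so cost is polynomial in the
output size rather than exponential in level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .peptide_chem import Atom, MolecularGraph

__all__ = [
    "MNADescriptor",
    "DescriptorSet",
    "atom_label",
    "mna_descriptor",
    "atom_descriptors",
    "descriptor_set",
    "descriptor_sets_by_level",
    "write_descriptor_dump",
]


@dataclass(frozen=True)
class MNADescriptor:
    text: str
    level: int


@dataclass(frozen=True)
class DescriptorSet:
    level: int
    descriptors: frozenset[str]

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __contains__(self, item: str) -> bool:
        return item in self.descriptors


def atom_label(atom: Atom) -> str:
    """Element symbol, ``-``-prefixed for acyclic atoms."""
    return atom.element if atom.in_ring else "-" + atom.element


def atom_descriptors(graph: MolecularGraph, level: int) -> list[str]:
    """Level-``level`` descriptor string for every atom, in atom-index order."""
    if level < 0:
        raise ValueError(f"descriptor level must be >= 0, got {level}")
    labels = [atom_label(a) for a in graph.atoms]
    adj = graph.adjacency()
    current = labels
    for _ in range(level):
        current = [
            f"{labels[i]}({''.join(sorted(current[j] for j in adj[i]))})"
            for i in range(len(labels))
        ]
    return current


def mna_descriptor(graph: MolecularGraph, atom_index: int, level: int) -> MNADescriptor:
    if not (0 <= atom_index < len(graph.atoms)):
        raise IndexError(f"atom index {atom_index} out of range")
    return MNADescriptor(atom_descriptors(graph, level)[atom_index], level)


def descriptor_set(graph: MolecularGraph, level: int) -> DescriptorSet:
    """Unique level-``level`` descriptors over all atoms.

    The result is invariant under any permutation of atom indices because
    every string is canonical (neighbor sub-strings sorted).
    """
    return DescriptorSet(level, frozenset(atom_descriptors(graph, level)))


def descriptor_sets_by_level(
    graph: MolecularGraph, levels: Sequence[int]
) -> dict[int, DescriptorSet]:
    """Descriptor sets at several levels from a single bottom-up pass."""
    if not levels:
        return {}
    if min(levels) < 0:
        raise ValueError("descriptor levels must be >= 0")
    wanted = set(levels)
    out: dict[int, DescriptorSet] = {}
    labels = [atom_label(a) for a in graph.atoms]
    adj = graph.adjacency()
    current = labels
    for lvl in range(max(levels) + 1):
        if lvl > 0:
            current = [
                f"{labels[i]}({''.join(sorted(current[j] for j in adj[i]))})"
                for i in range(len(labels))
            ]
        if lvl in wanted:
            out[lvl] = DescriptorSet(lvl, frozenset(current))
    return out


def write_descriptor_dump(
    entries: Iterable[tuple[str, DescriptorSet]], sink: TextIO | str | Path
) -> None:
    """One line per molecule: ``name<TAB>level<TAB>space-joined sorted descriptors``."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_descriptor_dump(entries, fh)
        return
    for name, dset in entries:
        sink.write(f"{name}\t{dset.level}\t{' '.join(sorted(dset.descriptors))}\n")
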