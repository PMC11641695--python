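"""Peptide sequences as explicit-hydrogen molecular graphs, plus SDF V3000 I/O.

One-letter sequences are condensed into a single polypeptide graph built
from per-residue templates: residues are joined by amide bonds (one water
removed per junction), the N-terminus is a neutral amine and the C-terminus
a neutral carboxylic acid, and every hydrogen is materialized as a graph
atom.  Atom order is deterministic: residues N-to-C, backbone heavy atoms
before side-chain heavy atoms, and each residue's hydrogens after its heavy
atoms.

Graphs can be stored in SD files using the MDL MOL V3000 connection table,
which has no atom-count ceiling, with arbitrary string data fields per
record (the secondary-structure class label travels in ``SSP_TYPE``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "SDFRecord",
    "InvalidSequenceError",
    "UnsupportedResidueError",
    "SDFParseError",
    "STANDARD_RESIDUES",
    "build_peptide_graph",
    "detect_ring_atoms",
    "write_sdf_v3000",
    "read_sdf_v3000",
    "read_sequences",
]


class InvalidSequenceError(ValueError):
    """Raised for an empty or otherwise unusable input sequence."""


class UnsupportedResidueError(ValueError):
    """Raised when a sequence letter is not one of the 20 standard residues."""

    def __init__(self, letter: str, position: int):
        self.letter = letter
        self.position = position  # 1-based
        super().__init__(
            f"unsupported residue {letter!r} at position {position}; "
            "only the 20 standard one-letter codes are accepted"
        )


class SDFParseError(ValueError):
    """Raised on malformed SDF/MOL V3000 input; carries the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class Atom:
    index: int
    element: str
    in_ring: bool = False


@dataclass
class Bond:
    a: int
    b: int
    order: int = 1

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class MolecularGraph:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""

    def add_atom(self, element: str) -> int:
        idx = len(self.atoms)
        self.atoms.append(Atom(idx, element))
        return idx

    def add_bond(self, a: int, b: int, order: int = 1) -> None:
        self.bonds.append(Bond(a, b, order))

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for bond in self.bonds:
            adj[bond.a].append(bond.b)
            adj[bond.b].append(bond.a)
        return adj

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
        return counts


@dataclass
class SDFRecord:
    graph: MolecularGraph
    properties: dict[str, str] = field(default_factory=dict)


# Per-residue templates.  Backbone heavy atoms N, CA, C, O are implicit in
# every residue; side chains list (name, element, hydrogen count) plus bonds
# (order 2 marks double bonds kept for SDF fidelity only).  Hydrogen counts
# are for an internal residue in neutral form; termini are adjusted during
# assembly (extra N-H at the N-terminus, hydroxyl O at the C-terminus).
_SC = {
    "A": ([("CB", "C", 3)], [("CA", "CB", 1)]),
    "R": (
        [
            ("CB", "C", 2),
            ("CG", "C", 2),
            ("CD", "C", 2),
            ("NE", "N", 1),
            ("CZ", "C", 0),
            ("NH1", "N", 1),
            ("NH2", "N", 2),
        ],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "CD", 1),
            ("CD", "NE", 1),
            ("NE", "CZ", 1),
            ("CZ", "NH1", 2),
            ("CZ", "NH2", 1),
        ],
    ),
    "N": (
        [("CB", "C", 2), ("CG", "C", 0), ("OD1", "O", 0), ("ND2", "N", 2)],
        [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "ND2", 1)],
    ),
    "D": (
        [("CB", "C", 2), ("CG", "C", 0), ("OD1", "O", 0), ("OD2", "O", 1)],
        [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "OD2", 1)],
    ),
    "C": ([("CB", "C", 2), ("SG", "S", 1)], [("CA", "CB", 1), ("CB", "SG", 1)]),
    "E": (
        [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 0), ("OE1", "O", 0), ("OE2", "O", 1)],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "CD", 1),
            ("CD", "OE1", 2),
            ("CD", "OE2", 1),
        ],
    ),
    "Q": (
        [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 0), ("OE1", "O", 0), ("NE2", "N", 2)],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "CD", 1),
            ("CD", "OE1", 2),
            ("CD", "NE2", 1),
        ],
    ),
    "G": ([], []),
    # Neutral His, N-epsilon tautomer.
    "H": (
        [
            ("CB", "C", 2),
            ("CG", "C", 0),
            ("ND1", "N", 0),
            ("CE1", "C", 1),
            ("NE2", "N", 1),
            ("CD2", "C", 1),
        ],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "ND1", 1),
            ("ND1", "CE1", 2),
            ("CE1", "NE2", 1),
            ("NE2", "CD2", 1),
            ("CD2", "CG", 2),
        ],
    ),
    "I": (
        [("CB", "C", 1), ("CG1", "C", 2), ("CG2", "C", 3), ("CD1", "C", 3)],
        [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1), ("CG1", "CD1", 1)],
    ),
    "L": (
        [("CB", "C", 2), ("CG", "C", 1), ("CD1", "C", 3), ("CD2", "C", 3)],
        [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1), ("CG", "CD2", 1)],
    ),
    "K": (
        [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 2), ("CE", "C", 2), ("NZ", "N", 2)],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "CD", 1),
            ("CD", "CE", 1),
            ("CE", "NZ", 1),
        ],
    ),
    "M": (
        [("CB", "C", 2), ("CG", "C", 2), ("SD", "S", 0), ("CE", "C", 3)],
        [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "SD", 1), ("SD", "CE", 1)],
    ),
    # Kekulized benzene ring.
    "F": (
        [
            ("CB", "C", 2),
            ("CG", "C", 0),
            ("CD1", "C", 1),
            ("CE1", "C", 1),
            ("CZ", "C", 1),
            ("CE2", "C", 1),
            ("CD2", "C", 1),
        ],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "CD1", 2),
            ("CD1", "CE1", 1),
            ("CE1", "CZ", 2),
            ("CZ", "CE2", 1),
            ("CE2", "CD2", 2),
            ("CD2", "CG", 1),
        ],
    ),
    # Pyrrolidine ring closes onto the backbone N; amide H removed below.
    "P": (
        [("CB", "C", 2), ("CG", "C", 2), ("CD", "C", 2)],
        [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "N", 1)],
    ),
    "S": ([("CB", "C", 2), ("OG", "O", 1)], [("CA", "CB", 1), ("CB", "OG", 1)]),
    "T": (
        [("CB", "C", 1), ("OG1", "O", 1), ("CG2", "C", 3)],
        [("CA", "CB", 1), ("CB", "OG1", 1), ("CB", "CG2", 1)],
    ),
    "W": (
        [
            ("CB", "C", 2),
            ("CG", "C", 0),
            ("CD1", "C", 1),
            ("NE1", "N", 1),
            ("CE2", "C", 0),
            ("CD2", "C", 0),
            ("CE3", "C", 1),
            ("CZ3", "C", 1),
            ("CH2", "C", 1),
            ("CZ2", "C", 1),
        ],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "CD1", 2),
            ("CD1", "NE1", 1),
            ("NE1", "CE2", 1),
            ("CE2", "CD2", 2),
            ("CD2", "CG", 1),
            ("CD2", "CE3", 1),
            ("CE3", "CZ3", 2),
            ("CZ3", "CH2", 1),
            ("CH2", "CZ2", 2),
            ("CZ2", "CE2", 1),
        ],
    ),
    "Y": (
        [
            ("CB", "C", 2),
            ("CG", "C", 0),
            ("CD1", "C", 1),
            ("CE1", "C", 1),
            ("CZ", "C", 0),
            ("OH", "O", 1),
            ("CE2", "C", 1),
            ("CD2", "C", 1),
        ],
        [
            ("CA", "CB", 1),
            ("CB", "CG", 1),
            ("CG", "CD1", 2),
            ("CD1", "CE1", 1),
            ("CE1", "CZ", 2),
            ("CZ", "OH", 1),
            ("CZ", "CE2", 1),
            ("CE2", "CD2", 2),
            ("CD2", "CG", 1),
        ],
    ),
    "V": (
        [("CB", "C", 1), ("CG1", "C", 3), ("CG2", "C", 3)],
        [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1)],
    ),
}

STANDARD_RESIDUES = frozenset(_SC)


def build_peptide_graph(sequence: str, name: str | None = None) -> MolecularGraph:
    """Convert a one-letter sequence into its condensed polypeptide graph.

    Residue templates are joined by amide bonds (losing one water per
    junction); termini are neutral (N-terminal NH2, C-terminal COOH) and
    all hydrogens are explicit.  Ring membership flags are resolved before
    the graph is returned.

    Raises
    ------
    InvalidSequenceError
        If the sequence is empty.
    UnsupportedResidueError
        If a letter is outside the 20 standard codes (1-based position
        reported).
    """
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    for pos, letter in enumerate(sequence, start=1):
        if letter not in _SC:
            raise UnsupportedResidueError(letter, pos)

    graph = MolecularGraph(name=name if name is not None else sequence)
    n_res = len(sequence)
    prev_c: int | None = None
    for i, letter in enumerate(sequence):
        side_heavy, side_bonds = _SC[letter]
        is_nterm = i == 0
        is_cterm = i == n_res - 1

        # amide N hydrogen count: proline ring N carries none internally
        n_h = 0 if letter == "P" else 1
        if is_nterm:
            n_h += 1
        ca_h = 2 if letter == "G" else 1

        heavy = [("N", "N", n_h), ("CA", "C", ca_h), ("C", "C", 0), ("O", "O", 0)]
        heavy.extend(side_heavy)
        if is_cterm:
            heavy.append(("OXT", "O", 1))

        local: dict[str, int] = {}
        for atom_name, element, _ in heavy:
            local[atom_name] = graph.add_atom(element)

        bonds = [("N", "CA", 1), ("CA", "C", 1), ("C", "O", 2)]
        bonds.extend(side_bonds)
        if is_cterm:
            bonds.append(("C", "OXT", 1))
        for a, b, order in bonds:
            graph.add_bond(local[a], local[b], order)
        if prev_c is not None:
            graph.add_bond(prev_c, local["N"], 1)
        prev_c = local["C"]

        for atom_name, _, h_count in heavy:
            for _ in range(h_count):
                h_idx = graph.add_atom("H")
                graph.add_bond(local[atom_name], h_idx, 1)

    detect_ring_atoms(graph)
    return graph


def detect_ring_atoms(graph: MolecularGraph) -> set[int]:
    """Return indices of atoms lying on at least one cycle; set ``in_ring``.

    An atom is cyclic iff it is an endpoint of some non-bridge edge; bridges
    are found with an iterative lowpoint DFS.
    """
    n = len(graph.atoms)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for ei, bond in enumerate(graph.bonds):
        adj[bond.a].append((bond.b, ei))
        adj[bond.b].append((bond.a, ei))

    disc = [-1] * n
    low = [0] * n
    is_bridge = [False] * len(graph.bonds)
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        stack: list[tuple[int, int, int]] = [(root, -1, 0)]  # node, parent edge, next child ptr
        while stack:
            node, pedge, ptr = stack.pop()
            if ptr == 0:
                disc[node] = low[node] = timer
                timer += 1
            if ptr < len(adj[node]):
                stack.append((node, pedge, ptr + 1))
                nxt, edge = adj[node][ptr]
                if edge == pedge:
                    continue
                if disc[nxt] == -1:
                    stack.append((nxt, edge, 0))
                else:
                    low[node] = min(low[node], disc[nxt])
            else:
                if pedge != -1:
                    bond = graph.bonds[pedge]
                    parent = bond.a if bond.b == node else bond.b
                    if low[node] > disc[parent]:
                        is_bridge[pedge] = True
                    low[parent] = min(low[parent], low[node])

    ring_atoms: set[int] = set()
    for ei, bond in enumerate(graph.bonds):
        if not is_bridge[ei]:
            ring_atoms.add(bond.a)
            ring_atoms.add(bond.b)
    for atom in graph.atoms:
        atom.in_ring = atom.index in ring_atoms
    return ring_atoms


# ---------------------------------------------------------------------------
# SDF (MOL V3000) I/O

_KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Mo Ru Rh Pd Ag Cd Sn Sb Te I Xe Cs Ba W Pt "
    "Au Hg Pb Bi".split()
)


def write_sdf_v3000(records: Iterable[SDFRecord], sink: TextIO | str | Path) -> None:
    """Serialize records as an SD file in the MOL V3000 dialect.

    All-zero coordinates are written; there is no atom-count ceiling.
    Data fields follow each connection table as ``>  <TAG>`` blocks.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_sdf_v3000(records, fh)
        return
    for rec in records:
        g = rec.graph
        sink.write(f"{g.name}\n  sspkit\n\n")
        sink.write("  0  0  0  0  0  0  0  0  0  0999 V3000\n")
        sink.write("M  V30 BEGIN CTAB\n")
        sink.write(f"M  V30 COUNTS {len(g.atoms)} {len(g.bonds)} 0 0 0\n")
        sink.write("M  V30 BEGIN ATOM\n")
        for atom in g.atoms:
            sink.write(f"M  V30 {atom.index + 1} {atom.element} 0 0 0 0\n")
        sink.write("M  V30 END ATOM\n")
        sink.write("M  V30 BEGIN BOND\n")
        for bi, bond in enumerate(g.bonds, start=1):
            sink.write(f"M  V30 {bi} {bond.order} {bond.a + 1} {bond.b + 1}\n")
        sink.write("M  V30 END BOND\n")
        sink.write("M  V30 END CTAB\n")
        sink.write("M  END\n")
        for tag, value in rec.properties.items():
            sink.write(f">  <{tag}>\n{value}\n\n")
        sink.write("$$$$\n")


def read_sdf_v3000(source: TextIO | str | Path) -> list[SDFRecord]:
    """Parse an SD file (MOL V3000 connection tables) into records.

    Raises :class:`SDFParseError` (with a line number) on malformed blocks
    or unknown element symbols.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_sdf_v3000(fh)
    lines = source.read().splitlines()
    records: list[SDFRecord] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        # skip blank padding between records
        while i < n_lines and not lines[i].strip():
            i += 1
        if i >= n_lines:
            break
        name = lines[i].strip()
        # find the start of the V3000 connection table
        ctab_start = None
        for j in range(i, min(i + 6, n_lines)):
            if lines[j].startswith("M  V30 BEGIN CTAB"):
                ctab_start = j
                break
        if ctab_start is None:
            raise SDFParseError("expected 'M  V30 BEGIN CTAB'", i + 1)
        i = ctab_start + 1
        if i >= n_lines or "COUNTS" not in lines[i]:
            raise SDFParseError("expected 'M  V30 COUNTS' after BEGIN CTAB", i + 1)
        counts = lines[i].split()
        try:
            n_atoms, n_bonds = int(counts[3]), int(counts[4])
        except (IndexError, ValueError):
            raise SDFParseError("malformed COUNTS line", i + 1) from None
        i += 1

        graph = MolecularGraph(name=name)
        i = _expect(lines, i, "M  V30 BEGIN ATOM")
        for _ in range(n_atoms):
            parts = lines[i].split()
            if len(parts) < 4 or parts[1] != "V30":
                raise SDFParseError("malformed atom line", i + 1)
            element = parts[3]
            if element not in _KNOWN_ELEMENTS:
                raise SDFParseError(f"unknown element symbol {element!r}", i + 1)
            graph.add_atom(element)
            i += 1
        i = _expect(lines, i, "M  V30 END ATOM")
        i = _expect(lines, i, "M  V30 BEGIN BOND")
        for _ in range(n_bonds):
            parts = lines[i].split()
            if len(parts) < 6:
                raise SDFParseError("malformed bond line", i + 1)
            try:
                order, a, b = int(parts[3]), int(parts[4]), int(parts[5])
            except ValueError:
                raise SDFParseError("malformed bond line", i + 1) from None
            if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
                raise SDFParseError("bond references missing atom", i + 1)
            graph.add_bond(a - 1, b - 1, order)
            i += 1
        i = _expect(lines, i, "M  V30 END BOND")
        i = _expect(lines, i, "M  V30 END CTAB")
        i = _expect(lines, i, "M  END")

        properties: dict[str, str] = {}
        while i < n_lines and lines[i].strip() != "$$$$":
            line = lines[i]
            match = re.match(r">\s*<(.+?)>", line)
            if match:
                tag = match.group(1)
                i += 1
                value_lines = []
                while i < n_lines and lines[i].strip() not in ("", "$$$$"):
                    value_lines.append(lines[i])
                    i += 1
                properties[tag] = "\n".join(value_lines)
            else:
                i += 1
        if i < n_lines and lines[i].strip() == "$$$$":
            i += 1
        detect_ring_atoms(graph)
        records.append(SDFRecord(graph, properties))
    return records


def _expect(lines: list[str], i: int, prefix: str) -> int:
    if i >= len(lines) or not lines[i].startswith(prefix):
        raise SDFParseError(f"expected {prefix!r}", i + 1)
    return i + 1


def read_sequences(source: TextIO | str | Path) -> list[tuple[str, str]]:
    """Read (name, sequence) pairs from FASTA or plain one-sequence-per-line text."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_sequences(fh)
    text = source.read()
    pairs: list[tuple[str, str]] = []
    if text.lstrip().startswith(">"):
        from io import StringIO

        from Bio import SeqIO

        for rec in SeqIO.parse(StringIO(text), "fasta"):
            pairs.append((rec.id, str(rec.seq).upper()))
    else:
        for k, line in enumerate(s for s in text.splitlines() if s.strip()):
            seq = line.strip().upper()
            pairs.append((f"seq{k + 1}", seq))
    return pairs


def _iter_graphs(records: Iterable[SDFRecord]) -> Iterator[MolecularGraph]:
    for rec in records:
        yield rec.graph
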