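"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import random

import pytest

from sspkit.peptide_chem import (
    Atom,
    Bond,
    MolecularGraph,
    build_peptide_graph,
    detect_ring_atoms,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def residue_graphs() -> dict[str, MolecularGraph]:
    return {aa: build_peptide_graph(aa) for aa in AMINO_ACIDS}


@pytest.fixture()
def water_graph() -> MolecularGraph:
    g = MolecularGraph(name="water")
    o = g.add_atom("O")
    g.add_bond(o, g.add_atom("H"))
    g.add_bond(o, g.add_atom("H"))
    detect_ring_atoms(g)
    return g


@pytest.fixture()
def methane_graph() -> MolecularGraph:
    g = MolecularGraph(name="methane")
    c = g.add_atom("C")
    for _ in range(4):
        g.add_bond(c, g.add_atom("H"))
    detect_ring_atoms(g)
    return g


def permute_graph(graph: MolecularGraph, rng: random.Random) -> MolecularGraph:
    """Relabeled isomorphic copy with atoms in a random order."""
    n = len(graph.atoms)
    perm = list(range(n))
    rng.shuffle(perm)  # perm[old] = new
    atoms = [None] * n
    for atom in graph.atoms:
        atoms[perm[atom.index]] = Atom(perm[atom.index], atom.element, atom.in_ring)
    bonds = [Bond(perm[b.a], perm[b.b], b.order) for b in graph.bonds]
    rng.shuffle(bonds)
    return MolecularGraph(atoms=atoms, bonds=bonds, name=graph.name)


def naive_mna(graph: MolecularGraph, atom_index: int, level: int) -> str:
    """Independent brute-force descriptor: plain recursion with explicit sorting."""
    adj = graph.adjacency()

    def label(i: int) -> str:
        a = graph.atoms[i]
        return a.element if a.in_ring else "-" + a.element

    def expand(i: int, lvl: int) -> str:
        if lvl == 0:
            return label(i)
        subs = sorted(expand(j, lvl - 1) for j in adj[i])
        return label(i) + "(" + "".join(subs) + ")"

    return expand(atom_index, level)


def brute_ring_atoms(graph: MolecularGraph) -> set[int]:
    """Ring atoms via an independent route: union of cycle-basis cycles."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(a.index for a in graph.atoms)
    g.add_edges_from((b.a, b.b) for b in graph.bonds)
    out: set[int] = set()
    for cycle in nx.cycle_basis(g):
        out.update(cycle)
    return out


def random_peptide(rng: random.Random, min_len: int = 1, max_len: int = 30) -> str:
    length = rng.randint(min_len, max_len)
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def brute_class_score(records, descriptors, cls: str, c: float) -> float:
    """From-scratch evidence score: recount everything, apply the formula."""
    n = len(records)
    n_a = sum(1 for r in records if cls in r[1])
    p0 = n_a / n
    total = 0.0
    for d in descriptors:
        nd = sum(1 for r in records if d in r[0])
        nad = sum(1 for r in records if d in r[0] and cls in r[1])
        total += 2.0 * (nad + c * p0) / (nd + c) - 1.0
    return total / len(descriptors)


def brute_auc(pairs) -> float:
    """Pairwise Mann-Whitney comparison, ties counted 1/2."""
    pos = [s for s, is_pos in pairs if is_pos]
    neg = [s for s, is_pos in pairs if not is_pos]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def make_dssp_text(
    residues: list[tuple[str, str, str]],
    header: bool = True,
    pdb_id: str = "1ABC",
) -> str:
    """Classic fixed-column DSSP text from (chain, aa, ss) rows; aa '!' is a break."""
    lines = []
    if header:
        lines.append("==== Secondary Structure Definition by the program DSSP ====")
        lines.append(f"HEADER    TEST PROTEIN                            01-JAN-20   {pdb_id}              .")
        lines.append("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N")
    for i, (chain, aa, ss) in enumerate(residues, start=1):
        if aa == "!":
            lines.append(f"{i:>5}" + " " * 8 + "!")
        else:
            lines.append(f"{i:>5}{i:>5} {chain} {aa}  {ss}   0   0    0")
    return "\n".join(lines) + "\n"
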