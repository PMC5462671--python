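"""Local-fragment detection and matrix restriction.

Seven chemically meaningful atom groups restrict a descriptor to a region
of the molecule: H-bond acceptors (A), aliphatic carbons (C), H-bond donors
(D), halogens (G), terminal methyl groups (M), aromatic carbons (P) and
heteroatoms (X); T denotes the whole molecule.  Restriction zeroes every
matrix row outside the fragment.  Because it is a plain row selection
applied after all other matrix transforms, restricting to the members of a
disjoint exhaustive partition and summing reproduces the unrestricted
matrix (and hence the total index) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph import MolecularGraph
from .matrices import SquareMatrix

__all__ = [
    "FragmentMask",
    "FRAGMENT_CODES",
    "detect_fragment",
    "restrict_matrix",
    "carbon_partition",
]

FRAGMENT_CODES = ("T", "A", "C", "D", "G", "M", "P", "X")

_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class FragmentMask:
    code: str
    level: str  # 'atom' | 'bond'
    members: frozenset[int]
    dimension: int

    def __post_init__(self) -> None:
        if self.level not in ("atom", "bond"):
            raise ValueError(f"unknown level {self.level!r}")
        if any(not (0 <= m < self.dimension) for m in self.members):
            raise ValueError("mask member out of range")

    def sorted_members(self) -> list[int]:
        return sorted(self.members)


def _atom_members(graph: MolecularGraph, code: str) -> set[int]:
    members: set[int] = set()
    for i, a in enumerate(graph.atoms):
        if code == "T":
            members.add(i)
        elif code == "A":
            if a.symbol in ("N", "O") and a.lone_pairs >= 1:
                members.add(i)
        elif code == "C":
            if a.symbol == "C" and not a.aromatic:
                members.add(i)
        elif code == "D":
            if a.symbol in ("N", "O") and _h_count(graph, i) >= 1:
                members.add(i)
        elif code == "G":
            if a.symbol in _HALOGENS:
                members.add(i)
        elif code == "M":
            if a.symbol == "C" and _h_count(graph, i) >= 3 and _heavy_degree(graph, i) == 1:
                members.add(i)
        elif code == "P":
            if a.symbol == "C" and a.aromatic:
                members.add(i)
        elif code == "X":
            if a.symbol not in ("C", "H"):
                members.add(i)
    return members


def _h_count(graph: MolecularGraph, i: int) -> int:
    """Attached hydrogens under either policy (implicit count + H neighbors)."""
    n = graph.atoms[i].n_h
    n += sum(1 for j in graph.neighbors(i) if graph.atoms[j].symbol == "H")
    return n


def _heavy_degree(graph: MolecularGraph, i: int) -> int:
    return sum(1 for j in graph.neighbors(i) if graph.atoms[j].symbol != "H")


def detect_fragment(graph: MolecularGraph, code: str, level: str = "atom") -> FragmentMask:
    """Membership mask for one fragment code at atom or bond level.

    A bond belongs to a fragment when at least one of its endpoints does.
    Empty masks are legal (e.g. halogens in an alkane).
    """
    if code not in FRAGMENT_CODES:
        raise KeyError(f"unknown fragment code {code!r}; options: {FRAGMENT_CODES}")
    atom_members = _atom_members(graph, code)
    if level == "atom":
        return FragmentMask(code, "atom", frozenset(atom_members), graph.n_atoms)
    if level != "bond":
        raise ValueError(f"unknown level {level!r}")
    bond_members = {
        e
        for e, b in enumerate(graph.bonds)
        if b.i in atom_members or b.j in atom_members
    }
    if code == "T":
        bond_members = set(range(graph.n_bonds))
    return FragmentMask(code, "bond", frozenset(bond_members), graph.n_bonds)


def restrict_matrix(Mk: SquareMatrix, mask: FragmentMask) -> SquareMatrix:
    """Keep the rows indexed by the mask members, zero all other rows."""
    level = "atom" if Mk.kind == "atom" else "bond"
    if mask.level != level:
        raise ValueError(f"mask level {mask.level!r} does not match matrix kind {Mk.kind!r}")
    if mask.dimension != Mk.n:
        raise ValueError(
            f"mask dimension {mask.dimension} does not match matrix size {Mk.n}"
        )
    if len(mask.members) == Mk.n:
        return Mk
    keep = np.zeros(Mk.n, dtype=bool)
    keep[list(mask.members)] = True
    return replace(Mk, values=np.where(keep[:, None], Mk.values, 0.0))


def carbon_partition(graph: MolecularGraph) -> list[FragmentMask]:
    """Disjoint exhaustive atom partition {P, C, X, remainder}.

    Aromatic carbons, aliphatic carbons and heteroatoms are pairwise
    disjoint by construction; the remainder (explicit hydrogens, or exotic
    atoms) completes the cover so fragment additivity can be checked as an
    exact identity.
    """
    p = _atom_members(graph, "P")
    c = _atom_members(graph, "C")
    x = _atom_members(graph, "X") - p - c
    rest = set(range(graph.n_atoms)) - p - c - x
    n = graph.n_atoms
    return [
        FragmentMask("P", "atom", frozenset(p), n),
        FragmentMask("C", "atom", frozenset(c), n),
        FragmentMask("X", "atom", frozenset(x), n),
        FragmentMask("rest", "atom", frozenset(rest), n),
    ]
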