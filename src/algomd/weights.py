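"""Atom- and bond-level property (weighting) vectors.

Ten atomic properties are available as weighting schemes: atomic mass (M),
Van der Waals volume (V), polarizability (P), Pauling electronegativity (E),
Ghose-Crippen logP contribution (A), Gasteiger-Marsili partial charge (C),
polar surface area contribution (PSA), molar refractivity contribution (R),
absolute hardness (H) and softness (S).  The unit vector (U) is reserved for
linear indices.

Element-level values (P, E, H, S) come from a bundled CSV table; mass and
Van der Waals radius come from RDKit's periodic table; the contribution
models (A, C, PSA, R) are evaluated with RDKit on the underlying molecule,
so they need a graph that was built from a real structure (not a hand-built
abstract graph).

Bond weights follow w_ij = w_i/delta_i + w_j/delta_j with delta the
multiplicity-weighted vertex degree under the active hydrogen policy.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors, rdPartialCharges

from .graph import MolecularGraph

__all__ = [
    "PropertyVector",
    "atomic_property_vector",
    "bond_property_vector",
    "apply_chirality",
    "PROPERTY_CODES",
    "default_chirality_modifier",
]

PROPERTY_CODES = ("M", "V", "P", "E", "A", "C", "PSA", "R", "H", "S")

_TABLE_BACKED = {"P": "polarizability", "E": "electronegativity", "H": "hardness"}


def _load_element_table() -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    with resources.files("algomd.data").joinpath("element_properties.csv").open() as fh:
        rows = [r for r in fh if not r.startswith("#")]
    for rec in csv.DictReader(rows):
        table[rec["symbol"]] = {
            k: float(v) for k, v in rec.items() if k != "symbol"
        }
    return table

_ELEMENTS = _load_element_table()
_PT = Chem.GetPeriodicTable()


@dataclass
class PropertyVector:
    values: np.ndarray
    code: str
    level: str  # 'atom' | 'bond'
    chirality: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("atom", "bond"):
            raise ValueError(f"unknown level {self.level!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _element_value(symbol: str, code: str) -> float:
    if code == "M":
        return _PT.GetAtomicWeight(symbol)
    if code == "V":
        r = _PT.GetRvdw(_PT.GetAtomicNumber(symbol))
        return 4.0 / 3.0 * math.pi * r ** 3
    rec = _ELEMENTS.get(symbol)
    if rec is None:
        raise KeyError(f"element {symbol} missing from the bundled property table")
    if code in ("P", "E", "H"):
        return rec[_TABLE_BACKED[code]]
    if code == "S":
        return 1.0 / rec["hardness"]
    raise KeyError(f"unknown element-level property {code!r}")


def _contribution_values(graph: MolecularGraph, code: str) -> np.ndarray:
    mol = graph.rdmol
    if mol is None:
        raise ValueError(
            f"property {code} needs an RDKit-backed molecule "
            "(contribution model); this graph has none"
        )
    mol = Chem.Mol(mol)
    if code == "C":
        rdPartialCharges.ComputeGasteigerCharges(mol)
        vals = np.array(
            [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
        )
        if graph.h_policy == "suppressed":
            # fold implicit-H charges into the heavy atom
            vals += np.array(
                [float(a.GetProp("_GasteigerHCharge")) for a in mol.GetAtoms()]
            )
        return vals
    if code in ("A", "R"):
        contribs = rdMolDescriptors._CalcCrippenContribs(mol)
        idx = 0 if code == "A" else 1
        return np.array([c[idx] for c in contribs])
    if code == "PSA":
        contribs = rdMolDescriptors._CalcTPSAContribs(mol)
        vals = np.zeros(mol.GetNumAtoms())
        vals[: len(contribs)] = contribs
        return vals
    raise KeyError(f"unknown contribution property {code!r}")


def atomic_property_vector(graph: MolecularGraph, code: str) -> PropertyVector:
    """Per-atom weighting vector for one property code (or U, the unit vector)."""
    if code == "U":
        return PropertyVector(np.ones(graph.n_atoms), "U", "atom")
    if code not in PROPERTY_CODES:
        raise KeyError(
            f"unknown property code {code!r}; options: {', '.join(PROPERTY_CODES)} or U"
        )
    if code in ("A", "C", "PSA", "R"):
        vals = _contribution_values(graph, code)
    else:
        vals = np.array([_element_value(a.symbol, code) for a in graph.atoms])
    if vals.shape[0] != graph.n_atoms:
        raise ValueError(
            f"property vector length {vals.shape[0]} != atom count {graph.n_atoms}"
        )
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite values in property {code} for {graph.source_id!r}")
    return PropertyVector(vals, code, "atom")


def bond_property_vector(graph: MolecularGraph, code: str) -> PropertyVector:
    """Per-bond weights w_ij = w_i/delta_i + w_j/delta_j, in bond-index order.

    delta is the sum of incident bond orders (loops and suppressed hydrogens
    excluded), so a double bond counts twice.
    """
    if graph.n_bonds < 1:
        raise ValueError(f"no bonds in {graph.source_id!r}")
    atom_vec = atomic_property_vector(graph, code)
    degrees = np.zeros(graph.n_atoms)
    for b in graph.bonds:
        degrees[b.i] += b.order
        degrees[b.j] += b.order
    vals = np.array(
        [
            atom_vec.values[b.i] / degrees[b.i] + atom_vec.values[b.j] / degrees[b.j]
            for b in graph.bonds
        ]
    )
    return PropertyVector(vals, code, "bond")


def default_chirality_modifier(factor: float, cip: str | None) -> float:
    """Default multiplicative stereocenter rule: (1+c) for R, (1-c) for S.

    A simple documented stand-in; the hook accepts any callable with this
    signature so a literature-exact trigonometric correction can be plugged
    in without API changes.
    """
    if cip == "R":
        return 1.0 + factor
    if cip == "S":
        return 1.0 - factor
    return 1.0


def apply_chirality(
    vec: PropertyVector,
    graph: MolecularGraph,
    factor: float,
    modifier=default_chirality_modifier,
) -> PropertyVector:
    """Apply a chirality correction factor c in [-3, 3] (0.25 steps).

    Atom-level vectors scale the stereocenter entries; bond-level vectors
    scale every bond incident to a stereocenter by the same rule.
    """
    steps = factor / 0.25
    if abs(factor) > 3 or abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"chirality factor {factor} not on the +-0.25 grid within [-3, 3]"
        )
    if factor == 0:
        return vec
    vals = vec.values.copy()
    if vec.level == "atom":
        for i, a in enumerate(graph.atoms):
            vals[i] *= modifier(factor, a.cip)
    else:
        for e, b in enumerate(graph.bonds):
            for end in (b.i, b.j):
                cip = graph.atoms[end].cip
                if cip is not None:
                    vals[e] *= modifier(factor, cip)
    return replace(vec, values=vals, chirality=factor)
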