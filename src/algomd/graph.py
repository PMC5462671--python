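"""Chemical graph model and structure input.

The central container is :class:`MolecularGraph`, an H-aware molecular
pseudograph: atoms carry element, formal charge, attached-H count, aromatic
flag, lone-pair count and an optional CIP stereodescriptor; bonds carry the
Kekulé bond order (1, 2 or 3) plus an aromatic flag.  Bond order plays the
role of edge multiplicity, so a double bond contributes two parallel edges
to the pseudograph.

Structures are read from MDL MOL/SDF files through RDKit; ring/aromaticity
perception, Kekulization and CIP assignment are delegated to it.  Hydrogen
handling is a policy, not a fixed choice: ``suppressed`` keeps only heavy
atoms (H folded into per-atom counts), ``explicit`` materializes H vertices.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("algomd")

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "read_molecules",
    "set_h_policy",
    "count_lone_pairs",
    "curate",
    "generate_fixtures",
    "random_molecules",
    "FIXTURE_REGISTRY",
]

H_POLICIES = ("suppressed", "explicit")

#: Valence-shell electron counts of the neutral atoms (standard Lewis model).
VALENCE_ELECTRONS = {
    "H": 1, "Li": 1, "Na": 1, "K": 1,
    "Be": 2, "Mg": 2, "Ca": 2, "Zn": 2,
    "B": 3, "Al": 3,
    "C": 4, "Si": 4,
    "N": 5, "P": 5, "As": 5,
    "O": 6, "S": 6, "Se": 6,
    "F": 7, "Cl": 7, "Br": 7, "I": 7,
}

#: Maximum plausible total valence used by the standalone valence check.
MAX_VALENCE = {
    "H": 1, "Li": 1, "Na": 1, "K": 1, "B": 4, "Al": 4,
    "C": 4, "Si": 4, "N": 4, "P": 5, "O": 3, "S": 6, "Se": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 3, "Be": 2, "Mg": 2, "Ca": 2, "Zn": 2,
}


@dataclass(frozen=True)
class Atom:
    symbol: str
    charge: int = 0
    n_h: int = 0
    aromatic: bool = False
    lone_pairs: int = 0
    cip: str | None = None  # 'R' / 'S' / None


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int = 1
    aromatic: bool = False


@dataclass
class MolecularGraph:
    atoms: list[Atom]
    bonds: list[Bond]
    h_policy: str = "suppressed"
    source_id: str = ""
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)
    valence_ok: bool = True

    def __post_init__(self) -> None:
        if self.h_policy not in H_POLICIES:
            raise ValueError(f"unknown H policy {self.h_policy!r}")
        n = len(self.atoms)
        for b in self.bonds:
            if b.i == b.j or not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references invalid atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, i: int) -> int:
        """Multiplicity-weighted vertex degree (sum of incident bond orders)."""
        return sum(b.order for b in self.bonds if i in (b.i, b.j))

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.symbol != "H")

    def neighbors(self, i: int) -> list[int]:
        return [b.j if b.i == i else b.i for b in self.bonds if i in (b.i, b.j)]


def _graph_from_rdkit(mol: Chem.Mol, h_policy: str, source_id: str = "") -> MolecularGraph:
    """Build a MolecularGraph from a sanitized RDKit Mol."""
    mol = Chem.Mol(mol)
    if h_policy == "suppressed":
        mol = Chem.RemoveHs(mol)
    else:
        mol = Chem.AddHs(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    atoms = []
    for a in mol.GetAtoms():
        cip = a.GetPropsAsDict().get("_CIPCode")
        # suppressed graphs fold H into a per-atom count; explicit graphs
        # carry H as vertices, so the count stays 0 to avoid double counting
        n_h = a.GetTotalNumHs() if h_policy == "suppressed" else 0
        atoms.append(
            Atom(
                symbol=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                n_h=n_h,
                aromatic=a.GetIsAromatic(),
                cip=cip if cip in ("R", "S") else None,
            )
        )
    bonds = []
    for b in kek.GetBonds():
        order = int(round(b.GetBondTypeAsDouble()))
        if order not in (1, 2, 3):
            raise ValueError(
                f"unsupported bond order {b.GetBondTypeAsDouble()} in {source_id!r}"
            )
        arom = mol.GetBondWithIdx(b.GetIdx()).GetIsAromatic()
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, arom))
    g = MolecularGraph(atoms, bonds, h_policy=h_policy, source_id=source_id, rdmol=mol)
    return count_lone_pairs(g)


def read_molecules(
    path: str | Path,
    fmt: str | None = None,
    h_policy: str = "suppressed",
    sanitize: bool = True,
) -> list[MolecularGraph]:
    """Read MDL MOL/SDF records into molecular graphs.

    One graph per record, in file order; the record index (and molecule
    title when present) is recorded as the source id.  Unparsable records
    are skipped with a logged warning so their positions stay visible in
    reports.  With ``sanitize=False`` chemically invalid records are kept
    (flagged ``valence_ok=False``) for later curation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "sdf"
    fmt = fmt.lower()
    if fmt not in ("mol", "sdf"):
        raise ValueError(f"unsupported format {fmt!r} (MOL or SDF)")

    text = path.read_text()
    if not text.strip():
        logger.warning("empty input file %s", path)
        return []

    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=sanitize, removeHs=False)
    graphs: list[MolecularGraph] = []
    for idx, mol in enumerate(supplier):
        source_id = f"{path.stem}#{idx}"
        if mol is None:
            logger.warning("record %d of %s could not be parsed; skipped", idx, path)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if name.strip():
            source_id = name.strip()
        try:
            graphs.append(_graph_from_rdkit(_ensure_sanitized(mol), h_policy, source_id))
        except Exception:
            g = _best_effort_graph(mol, h_policy, source_id)
            if g is None:
                logger.warning("record %d of %s invalid; skipped", idx, path)
            else:
                graphs.append(g)
    return graphs


def _ensure_sanitized(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    Chem.SanitizeMol(mol)
    return mol


def _best_effort_graph(mol: Chem.Mol, h_policy: str, source_id: str) -> MolecularGraph | None:
    """Graph for a record that fails sanitization (kept for curation)."""
    try:
        atoms = [
            Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetNumExplicitHs(), False)
            for a in mol.GetAtoms()
        ]
        bonds = [
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                 max(1, min(3, int(round(b.GetBondTypeAsDouble())))))
            for b in mol.GetBonds()
        ]
        return MolecularGraph(atoms, bonds, h_policy=h_policy,
                              source_id=source_id, rdmol=mol, valence_ok=False)
    except Exception:
        return None


def set_h_policy(graph: MolecularGraph, policy: str) -> MolecularGraph:
    """Return the graph under the requested hydrogen policy (idempotent)."""
    if policy not in H_POLICIES:
        raise ValueError(f"unknown H policy {policy!r}")
    if policy == graph.h_policy:
        return graph
    if graph.rdmol is not None and graph.valence_ok:
        g = _graph_from_rdkit(graph.rdmol, policy, graph.source_id)
        return g
    return _manual_h_policy(graph, policy)


def _manual_h_policy(graph: MolecularGraph, policy: str) -> MolecularGraph:
    if policy == "suppressed":
        keep = [i for i, a in enumerate(graph.atoms) if a.symbol != "H"]
        remap = {old: new for new, old in enumerate(keep)}
        extra_h = {i: 0 for i in keep}
        for b in graph.bonds:
            si, sj = graph.atoms[b.i].symbol, graph.atoms[b.j].symbol
            if si == "H" and sj != "H":
                extra_h[b.j] += 1
            elif sj == "H" and si != "H":
                extra_h[b.i] += 1
        atoms = [
            replace(graph.atoms[i], n_h=graph.atoms[i].n_h + extra_h[i]) for i in keep
        ]
        bonds = [
            Bond(remap[b.i], remap[b.j], b.order, b.aromatic)
            for b in graph.bonds
            if graph.atoms[b.i].symbol != "H" and graph.atoms[b.j].symbol != "H"
        ]
        g = MolecularGraph(atoms, bonds, "suppressed", graph.source_id,
                           graph.rdmol, graph.valence_ok)
    else:
        atoms = list(graph.atoms)
        bonds = list(graph.bonds)
        for i, a in enumerate(graph.atoms):
            for _ in range(a.n_h):
                atoms.append(Atom("H"))
                bonds.append(Bond(i, len(atoms) - 1, 1))
            atoms[i] = replace(a, n_h=0)
        g = MolecularGraph(atoms, bonds, "explicit", graph.source_id,
                           graph.rdmol, graph.valence_ok)
    return count_lone_pairs(g)


def count_lone_pairs(graph: MolecularGraph) -> MolecularGraph:
    """Annotate every atom with its Lewis-model lone-pair count.

    lone pairs = (valence electrons - formal charge - bonding electrons) / 2,
    where bonding electrons = sum of incident bond orders + attached H.
    Radicals (odd remainders) and elements without a tabulated valence count
    are rejected.
    """
    order_sum = [0] * graph.n_atoms
    for b in graph.bonds:
        order_sum[b.i] += b.order
        order_sum[b.j] += b.order
    atoms = []
    for i, a in enumerate(graph.atoms):
        if a.symbol not in VALENCE_ELECTRONS:
            raise ValueError(f"no valence-electron count tabulated for element {a.symbol}")
        nonbonding = VALENCE_ELECTRONS[a.symbol] - a.charge - order_sum[i] - a.n_h
        if nonbonding % 2 != 0 and nonbonding > 0:
            raise ValueError(
                f"odd electron count on atom {i} ({a.symbol}) of {graph.source_id!r}: "
                "radicals are unsupported"
            )
        atoms.append(replace(a, lone_pairs=max(0, nonbonding // 2)))
    return MolecularGraph(atoms, graph.bonds, graph.h_policy, graph.source_id,
                          graph.rdmol, graph.valence_ok)


# ---------------------------------------------------------------------------
# curation

CURATION_CHECKS = ("fragment", "duplicate", "valence")


def curate(
    graphs: Sequence[MolecularGraph],
    checks: Iterable[str] = CURATION_CHECKS,
) -> tuple[list[MolecularGraph], list[str]]:
    """Minimal structure curation: salt stripping, duplicates, valence.

    Returns the surviving graphs plus a plain-text report line for every
    modification or removal (nothing is ever dropped silently).  Duplicate
    detection uses RDKit canonical SMILES, which the report records.
    """
    checks = set(checks)
    unknown = checks - set(CURATION_CHECKS)
    if unknown:
        raise ValueError(f"unknown curation checks: {sorted(unknown)}")
    report: list[str] = []
    out: list[MolecularGraph] = []
    seen: set[str] = set()
    for g in graphs:
        gid = g.source_id or "<unnamed>"
        if "valence" in checks and not _valence_sane(g):
            report.append(f"{gid}: removed (valence)")
            continue
        if "fragment" in checks and g.rdmol is not None:
            frags = Chem.GetMolFrags(g.rdmol, asMols=True, sanitizeFrags=False)
            if len(frags) > 1:
                largest = max(frags, key=lambda m: m.GetNumHeavyAtoms())
                try:
                    g = _graph_from_rdkit(_ensure_sanitized(largest), g.h_policy, g.source_id)
                    report.append(f"{gid}: kept largest fragment "
                                  f"({largest.GetNumHeavyAtoms()} heavy atoms)")
                except Exception:
                    report.append(f"{gid}: removed (fragment salvage failed)")
                    continue
        if "duplicate" in checks and g.rdmol is not None:
            try:
                key = Chem.MolToSmiles(g.rdmol)
            except Exception:
                key = None
            if key is not None:
                if key in seen:
                    report.append(f"{gid}: removed (duplicate, canonical SMILES)")
                    continue
                seen.add(key)
        out.append(g)
    return out, report


def _valence_sane(g: MolecularGraph) -> bool:
    if not g.valence_ok and g.rdmol is not None:
        if Chem.DetectChemistryProblems(g.rdmol):
            return False
    for i, a in enumerate(g.atoms):
        limit = MAX_VALENCE.get(a.symbol)
        if limit is not None and g.degree(i) + a.n_h > limit + abs(a.charge):
            return False
    return True


# ---------------------------------------------------------------------------
# fixtures

# Isonicotinic acid (pyridine-4-carboxylic acid) with a fixed atom order:
# N1 C2 C3 C4 C5 C6 C7 O8(=O) O9(-OH).  Kekulé ring N1=C2, C3=C4, C5=C6.
_ISONICOTINIC_MOLBLOCK = """isonicotinic_acid
  algomd 2D

  9  9  0  0  0  0  0  0  0  0999 V2000
    0.0000    2.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8660   -1.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660   -1.5000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  4  7  1  0
  7  8  2  0
  7  9  1  0
M  END
"""

_SMILES_FIXTURES = {
    "pyridine": "c1ccncc1",
    "benzene": "c1ccccc1",
    "ethene": "C=C",
    "ethane": "CC",
    "chlorobenzene": "Clc1ccccc1",
    "propane": "CCC",
    "propanoic_acid": "CCC(=O)O",
    "methane": "C",
    "n_butane": "CCCC",
}

#: Linear alkane (path-graph) series, H-suppressed paths of 2..8 carbons.
_ALKANE_SERIES = {f"alkane_C{n}": "C" * n for n in range(2, 9)}

FIXTURE_REGISTRY = tuple(
    ["isonicotinic_acid"] + sorted(_SMILES_FIXTURES) + sorted(_ALKANE_SERIES)
)


def generate_fixtures(name: str, h_policy: str = "suppressed") -> list[MolecularGraph]:
    """Deterministically construct the named built-in molecule(s)."""
    if name == "all":
        return [generate_fixtures(n, h_policy)[0] for n in FIXTURE_REGISTRY]
    if name == "isonicotinic_acid":
        mol = Chem.MolFromMolBlock(_ISONICOTINIC_MOLBLOCK, removeHs=False)
        return [_graph_from_rdkit(mol, h_policy, "isonicotinic_acid")]
    smiles = _SMILES_FIXTURES.get(name) or _ALKANE_SERIES.get(name)
    if smiles is None:
        raise KeyError(
            f"unknown fixture {name!r}; registry: {', '.join(FIXTURE_REGISTRY)}"
        )
    mol = Chem.MolFromSmiles(smiles)
    return [_graph_from_rdkit(mol, h_policy, name)]


def random_molecules(
    count: int,
    seed: int,
    min_atoms: int = 4,
    max_atoms: int = 12,
) -> list[MolecularGraph]:
    """Seeded generator of random small organic graphs for property tests.

    Emulates drug-like heavy-atom skeletons: random trees over C/N/O/S/Cl
    with occasional extra ring-closing single bonds and double bonds where
    valence allows; hydrogens fill remaining valence.  Deterministic for a
    fixed seed.
    """
    rng = _random.Random(seed)
    elements = ["C", "C", "C", "C", "N", "O", "S", "Cl"]
    max_val = {"C": 4, "N": 3, "O": 2, "S": 2, "Cl": 1}
    out = []
    for m in range(count):
        n = rng.randint(min_atoms, max_atoms)
        symbols = ["C"] + [rng.choice(elements) for _ in range(n - 1)]
        used = [0] * n
        bonds: list[Bond] = []
        adjacency = set()
        for i in range(1, n):
            # attach to a previous atom with spare valence (C fallback)
            candidates = [j for j in range(i) if used[j] < max_val[symbols[j]]]
            if not candidates:
                symbols[i - 1] = "C"
                candidates = [i - 1]
            j = rng.choice(candidates)
            if used[j] >= max_val[symbols[j]]:
                symbols[j] = "C"
            order = 1
            if (rng.random() < 0.2 and used[i] + 2 <= max_val[symbols[i]]
                    and used[j] + 2 <= max_val[symbols[j]]):
                order = 2
            bonds.append(Bond(j, i, order))
            adjacency.add((j, i))
            used[i] += order
            used[j] += order
        # occasional ring closure
        if n >= 5 and rng.random() < 0.4:
            free = [i for i in range(n) if used[i] < max_val[symbols[i]]]
            rng.shuffle(free)
            for a, b in zip(free[::2], free[1::2]):
                lo, hi = min(a, b), max(a, b)
                if (lo, hi) not in adjacency and lo != hi:
                    bonds.append(Bond(lo, hi, 1))
                    adjacency.add((lo, hi))
                    used[lo] += 1
                    used[hi] += 1
                    break
        atoms = [
            Atom(sym, n_h=max_val[sym] - used[i])
            for i, sym in enumerate(symbols)
        ]
        g = MolecularGraph(list(atoms), bonds, "suppressed", f"random#{seed}#{m}")
        out.append(count_lone_pairs(g))
    return out
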