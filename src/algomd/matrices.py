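"""Pseudograph matrices: build, power, cut-offs and stochastic normalizations.

Two matrix families are supported.  The atom-based matrix (graph-theoretical
electronic-density matrix, GEDM) has off-diagonal entries equal to the bond
order between two atoms (edge multiplicity in the pseudograph) and a
configurable diagonal (aromatic loops and/or lone-pair counts).  The
bond-based edge-adjacency matrix (EAM) has entry 1 when two bonds share an
endpoint atom and an always-zero diagonal.

The raw integer matrix is "non-stochastic" (NS).  Three probabilistic
transforms are provided: simple stochastic (SS, row sums 1), double
stochastic (DS, row and column sums 1, obtained with the Sinkhorn-Knopp
alternate-scaling algorithm) and mutual probability (MP, grand sum 1).
Topological cut-offs retain the diagonal only (SRW), the off-diagonal only
(NSRW) or the entries whose topological distance lies in a window
[p_min, p_max] (Lag p).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.sparse import csr_matrix

from .graph import MolecularGraph

__all__ = [
    "SquareMatrix",
    "CutoffSpec",
    "MatrixError",
    "build_ns_atom_matrix",
    "build_ns_bond_matrix",
    "matrix_power",
    "topological_distances",
    "bond_topological_distances",
    "apply_cutoff",
    "normalize",
    "DIAG_MODES",
]

DIAG_MODES = ("none", "aromatic", "lone_pairs", "aromatic+lone_pairs")
MAX_POWER = 15


class MatrixError(ValueError):
    """Raised for matrix construction / normalization failures."""


@dataclass(frozen=True)
class CutoffSpec:
    """Topological constraint: KA (keep all), SRW, NSRW or LAG[p_min, p_max]."""

    type: str = "KA"
    p_min: int | None = None
    p_max: int | None = None

    def __post_init__(self) -> None:
        if self.type not in ("KA", "SRW", "NSRW", "LAG"):
            raise ValueError(f"unknown cut-off type {self.type!r}")
        if self.type == "LAG":
            if self.p_min is None or self.p_max is None:
                raise ValueError("LAG cut-off needs p_min and p_max")
            if not (0 <= self.p_min <= self.p_max):
                raise ValueError("LAG requires 0 <= p_min <= p_max")
        elif self.p_min is not None or self.p_max is not None:
            raise ValueError(f"{self.type} cut-off takes no distance window")

    @property
    def token(self) -> str:
        if self.type == "LAG":
            return f"LAG{self.p_min}-{self.p_max}"
        return self.type


KEEP_ALL = CutoffSpec("KA")


@dataclass
class SquareMatrix:
    """An n x n real matrix tagged with its provenance."""

    values: np.ndarray
    kind: str  # 'atom' | 'bond'
    normalization: str = "NS"
    power: int = 1
    cutoff: CutoffSpec = KEEP_ALL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("matrix must be square")
        if self.kind not in ("atom", "bond"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.normalization not in ("NS", "SS", "DS", "MP"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_ns_atom_matrix(graph: MolecularGraph, diag_mode: str = "none") -> SquareMatrix:
    """Non-stochastic atom-based pseudograph matrix (k = 1).

    Off-diagonal m_ij = bond order between atoms i and j (0 if non-adjacent;
    a triple bond gives 3).  Diagonal loops depend on ``diag_mode``:
    ``aromatic`` puts 1 on every atom carried by an aromatic ring,
    ``lone_pairs`` puts the Lewis lone-pair count, the combined mode sums
    both contributions.
    """
    if diag_mode not in DIAG_MODES:
        raise ValueError(f"unknown diag_mode {diag_mode!r}; options: {DIAG_MODES}")
    n = graph.n_atoms
    if n < 1:
        raise MatrixError("graph has no atoms")
    m = np.zeros((n, n))
    for b in graph.bonds:
        m[b.i, b.j] += b.order
        m[b.j, b.i] += b.order
    for i, a in enumerate(graph.atoms):
        d = 0.0
        if "aromatic" in diag_mode and a.aromatic:
            d += 1.0
        if "lone_pairs" in diag_mode:
            d += a.lone_pairs
        m[i, i] = d
    return SquareMatrix(m, kind="atom")


def build_ns_bond_matrix(graph: MolecularGraph) -> SquareMatrix:
    """Non-stochastic edge-adjacency matrix: 1 iff two bonds share an atom."""
    m_bonds = graph.n_bonds
    if m_bonds < 1:
        raise MatrixError(f"no edges in {graph.source_id!r}")
    e = np.zeros((m_bonds, m_bonds))
    for v in range(m_bonds):
        bv = graph.bonds[v]
        for w in range(v + 1, m_bonds):
            bw = graph.bonds[w]
            if {bv.i, bv.j} & {bw.i, bw.j}:
                e[v, w] = e[w, v] = 1.0
    return SquareMatrix(e, kind="bond")


def matrix_power(M: SquareMatrix, k: int) -> SquareMatrix:
    """Ordinary k-th matrix power (k = 0 gives the identity)."""
    if k < 0:
        raise ValueError("matrix power must be >= 0")
    if k > MAX_POWER:
        raise ValueError(f"matrix power limited to {MAX_POWER}")
    return replace(M, values=np.linalg.matrix_power(M.values, k), power=k)


def topological_distances(graph: MolecularGraph) -> np.ndarray:
    """Shortest-path edge counts on the simple underlying graph.

    Bond multiplicity is ignored; the diagonal is 0; disconnected pairs get
    the ``inf`` sentinel.
    """
    n = graph.n_atoms
    adj = np.zeros((n, n))
    for b in graph.bonds:
        adj[b.i, b.j] = adj[b.j, b.i] = 1
    return _bfs_distances(adj)


def bond_topological_distances(graph: MolecularGraph) -> np.ndarray:
    """Shortest-path distances on the bond (line) graph: adjacent bonds share an atom."""
    adj = build_ns_bond_matrix(graph).values
    return _bfs_distances(adj)


def _bfs_distances(adjacency: np.ndarray) -> np.ndarray:
    if adjacency.shape[0] == 1:
        return np.zeros((1, 1))
    return shortest_path(csr_matrix(adjacency), method="D", unweighted=True)


def apply_cutoff(Mk: SquareMatrix, D: np.ndarray, spec: CutoffSpec) -> SquareMatrix:
    """Filter matrix entries by the topological constraint ``spec``.

    KA keeps everything; SRW keeps the diagonal only; NSRW the off-diagonal
    only; LAG[p_min, p_max] keeps entries whose topological distance d_ij
    lies in the window (d_ii = 0, so any window with p_min >= 1 drops the
    diagonal).  Infinite-distance pairs are excluded by every LAG window.
    """
    if D.shape != Mk.values.shape:
        raise ValueError(
            f"dimension mismatch: matrix {Mk.values.shape} vs distances {D.shape}"
        )
    if spec.type == "KA":
        return replace(Mk, cutoff=spec)
    v = Mk.values.copy()
    n = v.shape[0]
    if spec.type == "SRW":
        v = np.diag(np.diag(v))
    elif spec.type == "NSRW":
        np.fill_diagonal(v, 0.0)
    else:  # LAG
        keep = (D >= spec.p_min) & (D <= spec.p_max) & np.isfinite(D)
        v = np.where(keep, v, 0.0)
    return replace(Mk, values=v, cutoff=spec)


def normalize(
    M: SquareMatrix,
    scheme: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> SquareMatrix:
    """Stochastic normalization of a non-negative matrix.

    SS divides each row by its sum (zero rows stay zero, so the result is
    row-stochastic on its support).  DS runs Sinkhorn-Knopp alternate
    row/column scaling until both row and column sums deviate from 1 by at
    most ``tol``; matrices without total support do not converge and raise.
    MP divides by the grand sum.
    """
    if scheme not in ("SS", "DS", "MP"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    v = M.values
    if np.any(v < 0):
        raise MatrixError("normalization requires non-negative entries")
    if scheme == "MP":
        total = v.sum()
        if total == 0:
            raise MatrixError("MP normalization of an all-zero matrix")
        return replace(M, values=v / total, normalization="MP")
    if scheme == "SS":
        rows = v.sum(axis=1, keepdims=True)
        if np.all(rows == 0):
            raise MatrixError("SS normalization of an all-zero matrix")
        safe = np.where(rows == 0, 1.0, rows)
        return replace(M, values=v / safe, normalization="SS")
    # DS: Sinkhorn-Knopp
    if np.any(v.sum(axis=1) == 0) or np.any(v.sum(axis=0) == 0):
        raise MatrixError("DS normalization: zero row or column (no total support)")
    x = v.astype(float).copy()
    for _ in range(max_iter):
        x = x / x.sum(axis=1, keepdims=True)
        x = x / x.sum(axis=0, keepdims=True)
        dev = max(
            np.abs(x.sum(axis=1) - 1).max(),
            np.abs(x.sum(axis=0) - 1).max(),
        )
        if dev <= tol:
            return replace(M, values=x, normalization="DS")
    raise MatrixError(
        f"Sinkhorn-Knopp did not converge in {max_iter} iterations "
        "(matrix lacks total support)"
    )
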