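"""Algebraic forms, per-atom/per-bond contributions and aggregation operators.

A descriptor is the value of a bilinear form x^T M y over a (possibly
powered, cut-off, normalized and fragment-restricted) pseudograph matrix M
and two property vectors; the quadratic form is the x = y special case and
the linear form the x = 1 special case.

The same total index decomposes into per-atom (per-bond) contributions,
called LOVIs/LOEIs (jointly LOVEIs): entry a is the bilinear form over the
matrix restricted to row a, which collapses to x_a * (M y)_a and lets the
whole vector be computed in one O(n^2) pass.  Summing the entries recovers
the vector-matrix-vector total exactly.

Aggregation operators turn a LOVEI vector into a single global or local
descriptor value.  Four groups are registered: norms (MH, EU, MK), means
(AM, GM, HM, P2, PN), statistical invariants (V, SD, SK, KT, MN, MX, RA,
MD, Q1, Q3) and the classical algorithms (TS total sum, KH Kier-Hall,
AC autocorrelation, GV gravitational), the latter needing the topological
distance matrix.  Evaluations that are mathematically undefined for a given
vector (e.g. the harmonic mean with a zero entry) yield the NA sentinel
(NaN), never an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrices import SquareMatrix
from .weights import PropertyVector

__all__ = [
    "LoveiVector",
    "AggregationOperator",
    "OPERATORS",
    "bilinear_form",
    "quadratic_form",
    "linear_form",
    "atom_level_lovei",
    "aggregate",
]

NA = float("nan")


@dataclass
class LoveiVector:
    values: np.ndarray
    level: str  # 'atom' | 'bond'
    provenance: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("atom", "bond"):
            raise ValueError(f"unknown level {self.level!r}")


def _check_dims(M: SquareMatrix, *vecs: PropertyVector) -> None:
    level = "atom" if M.kind == "atom" else "bond"
    for v in vecs:
        if v.level != level:
            raise ValueError(f"vector level {v.level!r} does not match matrix kind {M.kind!r}")
        if v.n != M.n:
            raise ValueError(f"vector length {v.n} does not match matrix size {M.n}")


def bilinear_form(M: SquareMatrix, x: PropertyVector, y: PropertyVector) -> float:
    """Total index x^T M y."""
    _check_dims(M, x, y)
    return float(x.values @ M.values @ y.values)


def quadratic_form(M: SquareMatrix, x: PropertyVector) -> float:
    """Quadratic index: the bilinear form with y = x."""
    return bilinear_form(M, x, x)


def linear_form(M: SquareMatrix, y: PropertyVector) -> float:
    """Linear index: the bilinear form with x the unit vector."""
    _check_dims(M, y)
    ones = PropertyVector(np.ones(M.n), "U", y.level)
    return bilinear_form(M, ones, y)


def atom_level_lovei(M: SquareMatrix, x: PropertyVector, y: PropertyVector) -> LoveiVector:
    """Per-atom (per-bond) contributions of the bilinear form.

    Entry a equals the bilinear form over the matrix whose rows other than a
    are zeroed, i.e. x_a * (M y)_a; the entire vector is one matrix-vector
    product, O(n^2) overall instead of the naive O(n^3) per-row restriction.
    """
    _check_dims(M, x, y)
    level = "atom" if M.kind == "atom" else "bond"
    vals = x.values * (M.values @ y.values)
    return LoveiVector(vals, level, provenance=(M.normalization, M.power, x.code, y.code))


@dataclass(frozen=True)
class AggregationOperator:
    code: str
    group: str  # 'norm' | 'mean' | 'statistical' | 'classical'
    needs_distances: bool = False


def _gm(v: np.ndarray) -> float:
    a = np.abs(v)
    if np.any(a == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(a))))


def _hm(v: np.ndarray) -> float:
    if np.any(v == 0):
        return NA
    return float(len(v) / np.sum(1.0 / v))


def _skew(v: np.ndarray) -> float:
    s = np.std(v)
    if s == 0:
        return NA
    return float(np.mean(((v - np.mean(v)) / s) ** 3))


def _kurt(v: np.ndarray) -> float:
    s = np.std(v)
    if s == 0:
        return NA
    return float(np.mean(((v - np.mean(v)) / s) ** 4) - 3.0)


def _bonded_pairs(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    bonded = D[iu] == 1
    return iu[0][bonded], iu[1][bonded]


def _kh(v: np.ndarray, D: np.ndarray) -> float:
    i, j = _bonded_pairs(D)
    if len(i) == 0:
        return NA
    prod = v[i] * v[j]
    if np.any(prod <= 0):
        return NA
    return float(np.sum(prod ** -0.5))


def _ac(v: np.ndarray, D: np.ndarray) -> float:
    i, j = _bonded_pairs(D)
    if len(i) == 0:
        return NA
    return float(np.mean(v[i] * v[j]))


def _gv(v: np.ndarray, D: np.ndarray) -> float:
    iu = np.triu_indices(D.shape[0], k=1)
    d = D[iu]
    ok = np.isfinite(d) & (d > 0)
    if not np.any(ok):
        return NA
    return float(np.sum(v[iu[0][ok]] * v[iu[1][ok]] / d[ok] ** 2))


_SIMPLE = {
    # norms
    "MH": lambda v: float(np.sum(np.abs(v))),
    "EU": lambda v: float(np.sqrt(np.sum(v ** 2))),
    "MK": lambda v: float(np.sum(np.abs(v) ** 3) ** (1.0 / 3.0)),
    # means
    "AM": lambda v: float(np.mean(v)),
    "GM": _gm,
    "HM": _hm,
    "P2": lambda v: float(np.sqrt(np.mean(v ** 2))),
    "PN": lambda v: float(np.cbrt(np.mean(v ** 3))),
    # statistical invariants
    "V": lambda v: float(np.var(v)),
    "SD": lambda v: float(np.std(v)),
    "SK": _skew,
    "KT": _kurt,
    "MN": lambda v: float(np.min(v)),
    "MX": lambda v: float(np.max(v)),
    "RA": lambda v: float(np.max(v) - np.min(v)),
    "MD": lambda v: float(np.median(v)),
    "Q1": lambda v: float(np.percentile(v, 25)),
    "Q3": lambda v: float(np.percentile(v, 75)),
    # classical
    "TS": lambda v: float(np.sum(v)),
}

_CLASSICAL_D = {"KH": _kh, "AC": _ac, "GV": _gv}

_GROUPS = {
    "MH": "norm", "EU": "norm", "MK": "norm",
    "AM": "mean", "GM": "mean", "HM": "mean", "P2": "mean", "PN": "mean",
    "V": "statistical", "SD": "statistical", "SK": "statistical",
    "KT": "statistical", "MN": "statistical", "MX": "statistical",
    "RA": "statistical", "MD": "statistical", "Q1": "statistical",
    "Q3": "statistical",
    "TS": "classical", "KH": "classical", "AC": "classical", "GV": "classical",
}

OPERATORS: dict[str, AggregationOperator] = {
    code: AggregationOperator(code, group, needs_distances=code in _CLASSICAL_D)
    for code, group in _GROUPS.items()
}


def aggregate(
    L: LoveiVector,
    op: str | AggregationOperator,
    D: np.ndarray | None = None,
) -> float:
    """Collapse a LOVEI vector to one descriptor value.

    Classical pairwise operators (KH, AC, GV) need the topological distance
    matrix of the matching level (atom distances for LOVIs, line-graph
    distances for LOEIs).  Undefined evaluations return NaN (written as the
    "NA" sentinel by the output writers).
    """
    code = op.code if isinstance(op, AggregationOperator) else op
    if code not in OPERATORS:
        raise KeyError(f"unknown aggregation operator {code!r}")
    spec = OPERATORS[code]
    v = np.asarray(L.values, dtype=float)
    if v.size == 0:
        return NA
    if not np.all(np.isfinite(v)):
        return NA
    if code in _CLASSICAL_D:
        if D is None:
            raise ValueError(f"operator {code} needs a distance matrix")
        if D.shape[0] != v.size:
            raise ValueError(
                f"distance matrix size {D.shape[0]} does not match LOVEI length {v.size}"
            )
        return _CLASSICAL_D[code](v, D)
    try:
        out = _SIMPLE[code](v)
    except (FloatingPointError, ZeroDivisionError, ValueError):
        return NA
    if out is None or (isinstance(out, float) and math.isinf(out)):
        return NA
    return out
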