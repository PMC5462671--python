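"""Descriptor engine: configuration, naming, batch computation and output.

A :class:`DescriptorConfig` describes a family of descriptors as the
Cartesian product of algebraic forms x matrix schemes/powers x cut-offs x
fragment scopes x property pairs x aggregation operators, under one
hydrogen policy and diagonal rule.  :func:`expand_config` turns it into a
deterministic, duplicate-free list of concrete specs; each spec has a
parseable name; :func:`compute_table` evaluates all specs for a molecule
set into a rectangular molecule x descriptor table.

Per-molecule failures (e.g. a normalization that is undefined for a given
matrix support) produce the NA sentinel and a log entry, never abort a run.
The table is bit-identical for any worker count because molecules are
independent and reassembled in input order.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from . import core, fragments, matrices, weights
from .graph import MolecularGraph, read_molecules, set_h_policy
from .matrices import KEEP_ALL, CutoffSpec, MatrixError, SquareMatrix

logger = logging.getLogger("algomd")

__all__ = [
    "DescriptorSpec",
    "DescriptorConfig",
    "ResultTable",
    "expand_config",
    "encode_name",
    "parse_name",
    "compute_descriptor",
    "compute_table",
    "write_table",
    "read_table",
    "save_project",
    "load_project",
    "run_batch",
]

FORMS = ("linear", "quadratic", "bilinear")
SCHEMES = ("NS", "SS", "DS", "MP")
_FORM_TOKEN = {"linear": "l", "quadratic": "q", "bilinear": "b"}
_TOKEN_FORM = {v: k for k, v in _FORM_TOKEN.items()}
_LEVEL_TOKEN = {"atom": "AB", "bond": "BB"}
_TOKEN_LEVEL = {v: k for k, v in _LEVEL_TOKEN.items()}
_H_TOKEN = {"suppressed": "nh", "explicit": "wh"}
_TOKEN_H = {v: k for k, v in _H_TOKEN.items()}
_DIAG_TOKEN = {
    "none": "nlp",
    "lone_pairs": "lp",
    "aromatic": "ar",
    "aromatic+lone_pairs": "arlp",
}
_TOKEN_DIAG = {v: k for k, v in _DIAG_TOKEN.items()}


@dataclass(frozen=True)
class DescriptorSpec:
    """One concrete descriptor: everything needed to compute and name it."""

    operator: str
    form: str
    k: int
    scheme: str
    cutoff: CutoffSpec
    scope: str
    level: str
    h_policy: str
    diag_mode: str
    x_code: str
    y_code: str
    chirality: float | None = None


@dataclass
class DescriptorConfig:
    forms: list[str] = field(default_factory=lambda: ["bilinear"])
    level: str = "atom"
    schemes: list[str] = field(default_factory=lambda: ["NS"])
    powers: list[int] = field(default_factory=lambda: [1])
    cutoffs: list[CutoffSpec] = field(default_factory=lambda: [KEEP_ALL])
    scopes: list[str] = field(default_factory=lambda: ["T"])
    property_pairs: list[tuple[str, str]] = field(default_factory=lambda: [("M", "M")])
    operators: list[str] = field(default_factory=lambda: ["TS"])
    h_policy: str = "suppressed"
    diag_mode: str = "none"
    chirality: float | None = None
    normalize_then_power: bool = False
    cutoff_after_normalization: bool = False
    float_digits: int = 6


def _validate_config(config: DescriptorConfig) -> None:
    for f in config.forms:
        if f not in FORMS:
            raise ValueError(f"unknown algebraic form {f!r}")
    if config.level not in ("atom", "bond"):
        raise ValueError(f"unknown level {config.level!r}")
    for s in config.schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown matrix scheme {s!r}")
    for k in config.powers:
        if not (0 <= k <= matrices.MAX_POWER):
            raise ValueError(f"matrix power {k} outside [0, {matrices.MAX_POWER}]")
    for sc in config.scopes:
        if sc not in fragments.FRAGMENT_CODES:
            raise ValueError(f"unknown fragment scope {sc!r}")
    for op in config.operators:
        if op not in core.OPERATORS:
            raise ValueError(f"unknown aggregation operator {op!r}")
    if config.h_policy not in _H_TOKEN:
        raise ValueError(f"unknown H policy {config.h_policy!r}")
    if config.diag_mode not in _DIAG_TOKEN:
        raise ValueError(f"unknown diag_mode {config.diag_mode!r}")
    valid_codes = set(weights.PROPERTY_CODES) | {"U"}
    for x, y in config.property_pairs:
        if x not in valid_codes or y not in valid_codes:
            raise ValueError(f"unknown property code in pair ({x}, {y})")


def expand_config(config: DescriptorConfig) -> list[DescriptorSpec]:
    """Deterministic, duplicate-free expansion into concrete descriptors.

    Each pair is matched to the forms it fits: quadratic takes identical-code
    pairs, linear takes (U, code), bilinear takes two proper property codes.
    A form left with no usable pair is rejected with a message rather than
    silently dropped.
    """
    _validate_config(config)

    def fits(form: str, x: str, y: str) -> bool:
        if form == "quadratic":
            return x == y and x != "U"
        if form == "linear":
            return x == "U" and y != "U"
        return "U" not in (x, y)

    for form in config.forms:
        if not any(fits(form, x, y) for x, y in config.property_pairs):
            wanted = {"quadratic": "(code, code) with identical codes",
                      "linear": "(U, code)",
                      "bilinear": "two property codes"}[form]
            raise ValueError(
                f"no property pair fits the {form} form (needs {wanted}); "
                f"pairs given: {config.property_pairs}"
            )
    specs: dict[DescriptorSpec, None] = {}
    for form, scheme, k, cut, scope, pair, op in itertools.product(
        config.forms,
        config.schemes,
        config.powers,
        config.cutoffs,
        config.scopes,
        config.property_pairs,
        config.operators,
    ):
        x, y = pair
        if not fits(form, x, y):
            continue
        spec = DescriptorSpec(
            operator=op, form=form, k=k, scheme=scheme, cutoff=cut,
            scope=scope, level=config.level, h_policy=config.h_policy,
            diag_mode=config.diag_mode, x_code=x, y_code=y,
            chirality=config.chirality,
        )
        specs[spec] = None
    if not specs:
        raise ValueError("configuration expands to no descriptors")
    return list(specs)


# ---------------------------------------------------------------------------
# descriptor names

def _prop_token(code: str) -> str:
    return code.lower()


def _prop_from_token(tok: str) -> str:
    code = tok.upper()
    if code not in set(weights.PROPERTY_CODES) | {"U"}:
        raise ValueError(f"unknown property token {tok!r}")
    return code


def encode_name(spec: DescriptorSpec) -> str:
    """Name grammar: OP_Fk_MAT_CUT_SCOPE_LEVEL_H-DIAG_x-y[_c<factor>]."""
    parts = [
        spec.operator,
        f"{_FORM_TOKEN[spec.form]}{spec.k}",
        spec.scheme,
        spec.cutoff.token,
        spec.scope,
        _LEVEL_TOKEN[spec.level],
        f"{_H_TOKEN[spec.h_policy]}-{_DIAG_TOKEN[spec.diag_mode]}",
        f"{_prop_token(spec.x_code)}-{_prop_token(spec.y_code)}",
    ]
    if spec.chirality is not None:
        parts.append(f"c{spec.chirality:+g}")
    return "_".join(parts)


def parse_name(name: str) -> DescriptorSpec:
    """Inverse of :func:`encode_name`; raises with the failing token position."""
    parts = name.split("_")
    if len(parts) not in (8, 9):
        raise ValueError(f"malformed descriptor name {name!r}: expected 8 or 9 tokens")

    def fail(pos: int, msg: str):
        raise ValueError(f"malformed descriptor name {name!r} at token {pos + 1}: {msg}")

    op = parts[0]
    if op not in core.OPERATORS:
        fail(0, f"unknown operator {op!r}")
    m = re.fullmatch(r"([lqb])(\d{1,2})", parts[1])
    if not m:
        fail(1, "expected form token like b2")
    form, k = _TOKEN_FORM[m.group(1)], int(m.group(2))
    if parts[2] not in SCHEMES:
        fail(2, f"unknown scheme {parts[2]!r}")
    cut_tok = parts[3]
    if cut_tok in ("KA", "SRW", "NSRW"):
        cut = CutoffSpec(cut_tok)
    else:
        m = re.fullmatch(r"LAG(\d+)-(\d+)", cut_tok)
        if not m:
            fail(3, f"unknown cut-off token {cut_tok!r}")
        cut = CutoffSpec("LAG", int(m.group(1)), int(m.group(2)))
    if parts[4] not in fragments.FRAGMENT_CODES:
        fail(4, f"unknown scope {parts[4]!r}")
    if parts[5] not in _TOKEN_LEVEL:
        fail(5, f"unknown level token {parts[5]!r}")
    m = re.fullmatch(r"(nh|wh)-(nlp|lp|ar|arlp)", parts[6])
    if not m:
        fail(6, f"unknown H/diagonal token {parts[6]!r}")
    props = parts[7].split("-")
    if len(props) != 2:
        fail(7, "expected x-y property token")
    try:
        x_code, y_code = _prop_from_token(props[0]), _prop_from_token(props[1])
    except ValueError as exc:
        fail(7, str(exc))
    chirality = None
    if len(parts) == 9:
        m2 = re.fullmatch(r"c([+-][\d.]+)", parts[8])
        if not m2:
            fail(8, f"unknown chirality token {parts[8]!r}")
        chirality = float(m2.group(1))
    return DescriptorSpec(
        operator=op, form=form, k=k, scheme=parts[2], cutoff=cut,
        scope=parts[4], level=_TOKEN_LEVEL[parts[5]],
        h_policy=_TOKEN_H[m.group(1)], diag_mode=_TOKEN_DIAG[m.group(2)],
        x_code=x_code, y_code=y_code, chirality=chirality,
    )


# ---------------------------------------------------------------------------
# computation

class _MoleculeContext:
    """Per-molecule caches for matrices, vectors, distances and masks."""

    def __init__(self, graph: MolecularGraph, config: DescriptorConfig):
        self.config = config
        self.graph = set_h_policy(graph, config.h_policy)
        self._matrices: dict[tuple, SquareMatrix] = {}
        self._base: dict[tuple, SquareMatrix] = {}
        self._vectors: dict[tuple, weights.PropertyVector] = {}
        self._distances: dict[str, np.ndarray] = {}
        self._masks: dict[tuple, fragments.FragmentMask] = {}

    def distances(self, level: str) -> np.ndarray:
        if level not in self._distances:
            if level == "atom":
                self._distances[level] = matrices.topological_distances(self.graph)
            else:
                self._distances[level] = matrices.bond_topological_distances(self.graph)
        return self._distances[level]

    def base_matrix(self, level: str, diag_mode: str) -> SquareMatrix:
        key = (level, diag_mode)
        if key not in self._base:
            if level == "atom":
                self._base[key] = matrices.build_ns_atom_matrix(self.graph, diag_mode)
            else:
                self._base[key] = matrices.build_ns_bond_matrix(self.graph)
        return self._base[key]

    def matrix(self, spec: DescriptorSpec) -> SquareMatrix:
        key = (spec.level, spec.diag_mode, spec.scheme, spec.k, spec.cutoff.token)
        if key in self._matrices:
            return self._matrices[key]
        cfg = self.config
        M = self.base_matrix(spec.level, spec.diag_mode)
        D = self.distances(spec.level)
        if cfg.normalize_then_power and spec.scheme != "NS":
            M = matrices.normalize(M, spec.scheme)
            M = matrices.matrix_power(M, spec.k)
            M = matrices.apply_cutoff(M, D, spec.cutoff)
        else:
            M = matrices.matrix_power(M, spec.k)
            if cfg.cutoff_after_normalization:
                if spec.scheme != "NS":
                    M = matrices.normalize(M, spec.scheme)
                M = matrices.apply_cutoff(M, D, spec.cutoff)
            else:
                M = matrices.apply_cutoff(M, D, spec.cutoff)
                if spec.scheme != "NS":
                    M = matrices.normalize(M, spec.scheme)
        self._matrices[key] = M
        return M

    def vector(self, code: str, level: str, chirality: float | None) -> weights.PropertyVector:
        key = (code, level, chirality)
        if key not in self._vectors:
            if level == "atom":
                v = weights.atomic_property_vector(self.graph, code)
            elif code == "U":
                v = weights.PropertyVector(np.ones(self.graph.n_bonds), "U", "bond")
            else:
                v = weights.bond_property_vector(self.graph, code)
            if chirality is not None and code != "U":
                v = weights.apply_chirality(v, self.graph, chirality)
            self._vectors[key] = v
        return self._vectors[key]

    def mask(self, scope: str, level: str) -> fragments.FragmentMask:
        key = (scope, level)
        if key not in self._masks:
            self._masks[key] = fragments.detect_fragment(self.graph, scope, level)
        return self._masks[key]


def compute_descriptor(ctx: _MoleculeContext, spec: DescriptorSpec) -> float:
    """Evaluate one descriptor for one molecule (NaN on undefined cases)."""
    try:
        M = ctx.matrix(spec)
        mask = ctx.mask(spec.scope, spec.level)
        if not mask.members:
            return core.NA
        M = fragments.restrict_matrix(M, mask)
        x = ctx.vector(spec.x_code, spec.level, spec.chirality)
        y = ctx.vector(spec.y_code, spec.level, spec.chirality)
        L = core.atom_level_lovei(M, x, y)
        members = mask.sorted_members()
        sub = core.LoveiVector(L.values[members], L.level, L.provenance)
        D = None
        if core.OPERATORS[spec.operator].needs_distances:
            D = ctx.distances(spec.level)[np.ix_(members, members)]
        return core.aggregate(sub, spec.operator, D)
    except (MatrixError, ValueError, KeyError) as exc:
        logger.info(
            "descriptor %s undefined for %s: %s",
            encode_name(spec), ctx.graph.source_id, exc,
        )
        return core.NA


@dataclass
class ResultTable:
    ids: list[str]
    names: list[str]
    values: np.ndarray  # molecules x descriptors

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError("result table is not rectangular")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)


def _compute_rows(args) -> list[np.ndarray]:
    graphs, config, specs = args
    rows = []
    for g in graphs:
        try:
            ctx = _MoleculeContext(g, config)
            rows.append(np.array([compute_descriptor(ctx, s) for s in specs]))
        except Exception as exc:  # molecule-level failure -> NA row
            logger.warning("molecule %s failed: %s", g.source_id, exc)
            rows.append(np.full(len(specs), core.NA))
    return rows


def compute_table(
    config: DescriptorConfig,
    molecules: Iterable[MolecularGraph],
    workers: int = 1,
) -> ResultTable:
    """Compute the molecule x descriptor table.

    Molecules are processed independently (optionally in parallel); rows
    appear in input order and the numbers are identical for any worker
    count.  A molecule whose computation fails entirely yields an NA row
    plus a log entry.
    """
    specs = expand_config(config)
    names = [encode_name(s) for s in specs]
    molecules = list(molecules)
    if not molecules:
        raise ValueError("no molecules to compute")
    ids = [g.source_id or f"mol#{i}" for i, g in enumerate(molecules)]
    if workers <= 1 or len(molecules) == 1:
        rows = _compute_rows((molecules, config, specs))
    else:
        chunks = [molecules[i::workers] for i in range(workers)]
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(
                pool.map(_compute_rows, [(c, config, specs) for c in chunks if c])
            )
        # reassemble input order from the round-robin split
        rows: list[np.ndarray] = [None] * len(molecules)  # type: ignore[list-item]
        for w, chunk_rows in enumerate(results):
            for pos, row in enumerate(chunk_rows):
                rows[w + pos * workers] = row
    return ResultTable(ids, names, np.vstack(rows))


# ---------------------------------------------------------------------------
# output formats

_SEPARATORS = {"csv": ",", "tsv": "\t", "ssv": " "}


def _fmt(value: float, digits: int) -> str:
    if math.isnan(value):
        return ""
    return f"{value:.{digits}g}"


def write_table(
    table: ResultTable,
    path: str | Path,
    fmt: str = "csv",
    float_digits: int = 6,
) -> None:
    """Write CSV/TSV/SSV (header + id column) or ARFF (numeric + '?' for NA).

    Floats use fixed significant-digit formatting so repeated runs produce
    byte-identical files.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt in _SEPARATORS:
        sep = _SEPARATORS[fmt]
        na = "NA" if fmt == "ssv" else ""
        with path.open("w") as fh:
            fh.write(sep.join(["id"] + list(table.names)) + "\n")
            for mol_id, row in zip(table.ids, table.values):
                cells = [_fmt(v, float_digits) or na for v in row]
                fh.write(sep.join([mol_id] + cells) + "\n")
    elif fmt == "arff":
        with path.open("w") as fh:
            fh.write("@RELATION descriptors\n\n")
            fh.write("@ATTRIBUTE id STRING\n")
            for name in table.names:
                fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
            fh.write("\n@DATA\n")
            for mol_id, row in zip(table.ids, table.values):
                cells = [_fmt(v, float_digits) or "?" for v in row]
                fh.write(",".join([mol_id] + cells) + "\n")
    else:
        raise ValueError(f"unknown output format {fmt!r} (csv, tsv, ssv, arff)")


def read_table(path: str | Path, fmt: str | None = None) -> ResultTable:
    """Read a table previously written by :func:`write_table`."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    fmt = fmt.lower()
    if fmt in _SEPARATORS:
        df = pd.read_csv(
            path, sep=_SEPARATORS[fmt], na_values=["NA"], keep_default_na=True
        )
        ids = [str(v) for v in df.iloc[:, 0]]
        names = list(df.columns[1:])
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        return ResultTable(ids, names, values)
    if fmt == "arff":
        names: list[str] = []
        data: list[list[str]] = []
        in_data = False
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            lower = line.lower()
            if lower.startswith("@attribute"):
                names.append(line.split(None, 2)[1])
            elif lower.startswith("@data"):
                in_data = True
            elif in_data:
                data.append(line.split(","))
        ids = [row[0] for row in data]
        values = np.array(
            [[float("nan") if c == "?" else float(c) for c in row[1:]] for row in data]
        )
        return ResultTable(ids, names[1:], values)
    raise ValueError(f"unknown input format {fmt!r}")


# ---------------------------------------------------------------------------
# project files (XML)

PROJECT_SCHEMA_VERSION = "1"


def save_project(config: DescriptorConfig, path: str | Path) -> None:
    """Serialize a configuration to a versioned XML project file."""
    _validate_config(config)
    root = etree.Element("descriptor-project", version=PROJECT_SCHEMA_VERSION)

    def add_list(tag: str, item_tag: str, items: Sequence[str]) -> None:
        parent = etree.SubElement(root, tag)
        for it in items:
            etree.SubElement(parent, item_tag).text = str(it)

    add_list("forms", "form", config.forms)
    etree.SubElement(root, "level").text = config.level
    add_list("schemes", "scheme", config.schemes)
    add_list("powers", "power", [str(k) for k in config.powers])
    cuts = etree.SubElement(root, "cutoffs")
    for c in config.cutoffs:
        el = etree.SubElement(cuts, "cutoff", type=c.type)
        if c.type == "LAG":
            el.set("p_min", str(c.p_min))
            el.set("p_max", str(c.p_max))
    add_list("scopes", "scope", config.scopes)
    pairs = etree.SubElement(root, "pairs")
    for x, y in config.property_pairs:
        etree.SubElement(pairs, "pair", x=x, y=y)
    add_list("operators", "operator", config.operators)
    etree.SubElement(root, "h-policy").text = config.h_policy
    etree.SubElement(root, "diag-mode").text = config.diag_mode
    if config.chirality is not None:
        etree.SubElement(root, "chirality").text = repr(config.chirality)
    opts = etree.SubElement(root, "options")
    opts.set("normalize_then_power", str(config.normalize_then_power).lower())
    opts.set("cutoff_after_normalization", str(config.cutoff_after_normalization).lower())
    opts.set("float_digits", str(config.float_digits))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


_KNOWN_ELEMENTS = {
    "forms", "level", "schemes", "powers", "cutoffs", "scopes",
    "pairs", "operators", "h-policy", "diag-mode", "chirality", "options",
}


def load_project(path: str | Path) -> DescriptorConfig:
    """Load and validate an XML project file (inverse of :func:`save_project`)."""
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"project file {path} is not well-formed XML: {exc}") from exc
    if root.tag != "descriptor-project":
        raise ValueError(f"unexpected root element <{root.tag}>")
    version = root.get("version")
    if version != PROJECT_SCHEMA_VERSION:
        raise ValueError(f"unsupported project schema version {version!r}")
    for child in root:
        if child.tag not in _KNOWN_ELEMENTS:
            logger.warning("ignoring unknown project element <%s>", child.tag)

    def texts(parent_tag: str, item_tag: str) -> list[str]:
        parent = root.find(parent_tag)
        if parent is None:
            raise ValueError(f"project file missing <{parent_tag}>")
        return [el.text.strip() for el in parent.findall(item_tag)]

    cutoffs = []
    cuts = root.find("cutoffs")
    if cuts is None:
        raise ValueError("project file missing <cutoffs>")
    for el in cuts.findall("cutoff"):
        ctype = el.get("type")
        try:
            if ctype == "LAG":
                cutoffs.append(CutoffSpec("LAG", int(el.get("p_min")), int(el.get("p_max"))))
            else:
                cutoffs.append(CutoffSpec(ctype))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid <cutoff> element: {exc}") from exc
    pairs = []
    pair_el = root.find("pairs")
    if pair_el is None:
        raise ValueError("project file missing <pairs>")
    for el in pair_el.findall("pair"):
        pairs.append((el.get("x"), el.get("y")))
    opts = root.find("options")
    chir_el = root.find("chirality")
    config = DescriptorConfig(
        forms=texts("forms", "form"),
        level=(root.findtext("level") or "atom").strip(),
        schemes=texts("schemes", "scheme"),
        powers=[int(t) for t in texts("powers", "power")],
        cutoffs=cutoffs,
        scopes=texts("scopes", "scope"),
        property_pairs=pairs,
        operators=texts("operators", "operator"),
        h_policy=(root.findtext("h-policy") or "suppressed").strip(),
        diag_mode=(root.findtext("diag-mode") or "none").strip(),
        chirality=float(chir_el.text) if chir_el is not None else None,
        normalize_then_power=(opts is not None and opts.get("normalize_then_power") == "true"),
        cutoff_after_normalization=(
            opts is not None and opts.get("cutoff_after_normalization") == "true"
        ),
        float_digits=int(opts.get("float_digits", "6")) if opts is not None else 6,
    )
    try:
        _validate_config(config)
    except ValueError as exc:
        raise ValueError(f"invalid project file {path}: {exc}") from exc
    return config


# ---------------------------------------------------------------------------
# batch processing

MAX_BATCH_TASKS = 8


def run_batch(
    tasks: Sequence[tuple[Sequence[str | Path], Sequence[str | Path]]],
    workers: int = 1,
) -> tuple[dict[tuple[int, str, str], ResultTable], list[str]]:
    """Run up to eight independent (datasets x projects) tasks.

    Each task pairs every dataset with every project file; failures are
    isolated per (dataset, project) pair and reported in the consolidated
    log, never aborting sibling tasks.
    """
    if not 1 <= len(tasks) <= MAX_BATCH_TASKS:
        raise ValueError(
            f"batch accepts 1..{MAX_BATCH_TASKS} tasks, got {len(tasks)}"
        )
    results: dict[tuple[int, str, str], ResultTable] = {}
    report: list[str] = []
    for t, (datasets, projects) in enumerate(tasks):
        for ds in datasets:
            for pj in projects:
                key = (t, str(ds), str(pj))
                try:
                    config = load_project(pj)
                    mols = read_molecules(ds, h_policy=config.h_policy)
                    results[key] = compute_table(config, mols, workers=workers)
                    report.append(f"task {t}: {ds} x {pj}: ok "
                                  f"({len(results[key].ids)} molecules)")
                except Exception as exc:
                    report.append(f"task {t}: {ds} x {pj}: FAILED ({exc})")
    return results, report
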