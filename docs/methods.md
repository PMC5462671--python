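# Methods

This note documents the model, the numerical choices and the deliberate
design decisions behind `algomd`, in the spirit of a statistics package's
methods appendix.  Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Molecular model

A molecule is a pseudograph over heavy atoms (or all atoms, under the
explicit-H policy): bond order after Kekulization is edge multiplicity
(1–3), and diagonal loops are optional annotations.  RDKit performs
parsing, sanitization, aromaticity perception, Kekulization and CIP
assignment; the package's own `MolecularGraph` is a plain, toolkit-agnostic
record of the result so that matrices and invariants can also be exercised
on hand-built or randomly generated abstract graphs.

**Hydrogen policy.**  `suppressed` folds H into per-atom counts;
`explicit` materializes H vertices (whose attached-H count is then zero —
they are vertices, not counts; both representations conserve heavy atoms
and heavy-bond orders, which is tested as a round-trip).

**Lone pairs.**  The paper-level definition is operationalized with the
standard Lewis model: `lp = max(0, (VE − q − Σ bond orders − n_H) / 2)`
with VE the neutral-atom valence-electron count and q the formal charge.
Positive odd remainders (radicals) are rejected rather than guessed.
Examples covered by tests: pyridine-type N → 1, hydroxyl/carbonyl O → 2,
tetravalent C → 0, Cl → 3.

**Diagonal rule.**  `diag_mode=aromatic` puts 1 on every atom of an
aromatic ring (perception-based, not resonance counting);
`diag_mode=lone_pairs` puts the lone-pair count; the combined mode sums
both.  An additive rule keeps the two switches independent.

## Matrix pipeline

Default order: build NS (k = 1) → matrix power k → cut-off → normalization
→ fragment restriction.  Normalizing after the cut-off keeps the
stochastic invariants true on the retained support, and restricting last
makes fragment additivity an exact theorem (see below).  Because the
opposite orders are also defensible, two switches are provided:
`normalize_then_power` (normalize M¹, then power the stochastic matrix)
and `cutoff_after_normalization`; both default off.

* **SS**: rows divided by row sums; all-zero rows stay zero (row-stochastic
  on support).  An all-zero matrix is an error.
* **DS**: Sinkhorn–Knopp alternate row/column scaling; tolerance 1e-8 on
  the maximum row/column-sum deviation, 1000 iterations.  Matrices without
  total support (e.g. odd powers of bipartite skeletons, or any matrix
  with a zero row) cannot be doubly stochastic; the failure is reported
  per molecule and surfaces as an NA descriptor value, never a crash.
  Even powers of a connected skeleton have a positive diagonal and always
  converge, which is how the invariant is exercised.
* **MP**: division by the grand sum; symmetric input gives symmetric
  output with total 1.

**Distances** are BFS shortest-path edge counts on the simple underlying
graph (multiplicity and loops ignored); disconnected pairs carry an `inf`
sentinel and are excluded by every Lag window.  Lag windows use
`p_min ≤ d_ij ≤ p_max` with `d_ii = 0`, so `Lag [2,5]` drops the diagonal
and bonded pairs.  Powers up to k = 15 are supported (k = 0 is the
identity).

## Weights

Element-level values (polarizability, Pauling electronegativity, absolute
hardness; softness = 1/hardness) are bundled as a versioned CSV with their
sources named in its header; mass and the Van der Waals radius (volume =
4/3 π r³) come from RDKit's periodic table; the contribution-based
properties (Ghose–Crippen logP and molar refractivity, Gasteiger–Marsili
charges, topological PSA) are computed by RDKit's standard implementations
of those published models.  Under the suppressed-H policy, Gasteiger H
charges are folded into their heavy atom so the vector still sums to the
net formal charge (tested to 1e-3).  Cross-toolkit drift in these
contribution models is expected and only affects absolute descriptor
values, not any of the algebraic invariants.

Bond weights follow `w_ij = w_i/δ_i + w_j/δ_j`, where δ sums incident bond
orders under the active H policy and excludes diagonal loops; suppressed
hydrogens do not contribute to δ.

**Chirality hook.**  The correction factor 𝔠 lives on a ±0.25 grid in
[-3, 3].  The default modifier multiplies R-center entries by (1 + 𝔠) and
S-center entries by (1 − 𝔠) — an explicitly labeled, pluggable stand-in,
not a literature-exact trigonometric correction; any callable
`(factor, cip) -> multiplier` can replace it without API change.  Vectors
computed with 𝔠 ≠ 0 carry the factor as provenance, and it appears as a
trailing name token.

## Fragments and additivity

Atom-level membership rules (the minimal standard readings of the seven
group names, each fixed by unit tests): A = N/O with ≥ 1 lone pair;
C = non-aromatic carbon; D = N/O bonded to ≥ 1 H; G = F/Cl/Br/I;
M = carbon with ≥ 3 attached H and exactly one heavy neighbor;
P = aromatic carbon; X = any heavy non-carbon.  A bond belongs to a
fragment when at least one endpoint does (the one-endpoint reading is a
choice; the alternative both-endpoint rule would break bond-level
coverage by T-partitions).

Restriction zeroes the rows outside the mask.  Row selection (rather than
row-and-column) is the unique rule under which fragment matrices — and
hence fragment indices — sum *exactly* to the total across any disjoint
exhaustive partition, for every scheme and cut-off, because it commutes
with entrywise addition after all other transforms.  The test partition is
{aromatic C, aliphatic C, heteroatoms, remainder}.

## LOVEIs and aggregation

The per-atom contribution of `x̄ᵀ M ȳ` is the form over the single-row
restriction, which collapses to `L_a = x_a (M ȳ)_a`; the whole vector is
one matrix–vector product (O(n²)) and is verified entrywise against the
naive O(n³) per-atom-matrix computation.  `TS(L) = x̄ᵀ M ȳ` holds to
1e-9 across schemes, cut-offs and property pairs.

Operator registry (22 codes in four groups):

| group | codes | notes |
|---|---|---|
| norms | MH, EU, MK | Manhattan Σ\|Lᵢ\|, Euclidean, Minkowski p = 3 |
| means | AM, GM, HM, P2, PN | GM uses \|Lᵢ\|; PN = ∛(mean of cubes) |
| statistical | V, SD, SK, KT, MN, MX, RA, MD, Q1, Q3 | population moments; KT is excess kurtosis; quartiles by linear interpolation |
| classical | TS, KH, AC, GV | KH = Σ_{d=1} (LᵢLⱼ)^(−1/2); AC = mean over d = 1 pairs; GV = Σ_{i<j} LᵢLⱼ/d²ᵢⱼ |

Classical operators always use the simple-graph topological distances of
the matching level (line-graph distances for bond-level vectors).
AC is defined as the *mean* over bonded pairs (the half-sum alternative is
a documented choice, differing only by the bond-count factor).  Undefined
evaluations — harmonic mean with a zero entry, KH with a non-positive pair
product, skewness/kurtosis of a constant vector, empty fragments — yield
the NA sentinel (NaN internally; "" in CSV, "NA" in SSV, "?" in ARFF) and
a log line, never an exception.

When a fragment scope is active, operators aggregate over the fragment
members' entries only; structural zeros outside the mask are excluded so
mean-like operators remain meaningful, while TS over members still equals
the local-fragment total index.

## Engine

Config expansion is the deterministic Cartesian product of forms × schemes
× powers × cut-offs × scopes × pairs × operators, deduplicated, with each
property pair matched to the forms it fits (quadratic: identical codes;
linear: (U, code); bilinear: two proper codes) and an error if a form is
left with no pair.  The name grammar

```
<OP>_<F><k>_<MAT>_<CUT>_<SCOPE>_<LEVEL>_<H>-<DIAG>_<x>-<y>[_c<factor>]
e.g.  EU_q3_MP_LAG2-5_X_AB_nh-nlp_m-m
```

is original to this package (the historical token schemes of this
descriptor family are not fully documented); `parse ∘ encode` is the
identity, tested on randomized specs.  Levels are AB (atom-based) / BB
(bond-based); H tokens nh/wh; diagonal tokens nlp/lp/ar/arlp.

Molecules are independent: the table is computed per molecule (optionally
over a process pool) and reassembled in input order, so the output is
identical for any worker count.  Floats are written with fixed significant
digits (default 6, configurable) for byte-reproducible files.  Project
files are a small versioned XML schema of this package; unknown elements
warn and are ignored, invalid values (e.g. powers outside [0, 15]) are
errors.  Batch mode accepts at most eight independent tasks, each pairing
datasets with project files, with per-pair failure isolation.

Curation implements three documented checks — keep-largest-fragment,
duplicate removal by RDKit canonical SMILES (the canonicalization choice
is recorded in the report), and valence sanity — and reports every removal.

## Variability analysis

`SE = −Σ pᵢ log₂ pᵢ` over descriptor-value bins, NA values dropped with a
count.  Default B = N bins (one per molecule), making log₂N the attainable
maximum.  Two discretization rules: equal-width over [min, max]
(right-closed; default) and equal-count (quantile).  The exact
discretization used by the historical entropy tooling is not published, so
cross-software entropy comparisons are qualitative; the equal-count rule
with B = N reproduces the log₂N bound exactly on all-distinct values,
which anchors the analytic checks (log₂1963 ≈ 10.94 bits; a 9.0-bit
threshold is 82% of that maximum; log₂41 ≈ 5.36 bits with a 4.62-bit
threshold at 86%).

## Problem sizes and scope

The test suite and the acceptance script run on the built-in fixture set
(16 named molecules, ≤ 9 heavy atoms) plus seeded random heavy-atom
skeletons of 4–12 atoms (100 molecules for the invariant sweeps), with
powers k ≤ 5 and the four cut-off types.  The random generator emulates
drug-like heavy-atom skeletons — random trees over C/N/O/S/Cl with
occasional double bonds and ring closures, valence-complete by
construction — and deliberately omits aromatic systems, charges and
stereocenters, which are exercised through the RDKit-backed named
fixtures instead.  Passing invariants on these sets therefore validate
the algebra and the pipeline wiring, not the chemical realism of any
particular property table.

## Known limitations

* MDL V3000, polymers/organometallics and tautomer standardization are out
  of scope; structure curation is the minimal three-check subset.
* The chirality modifier is a stand-in rule, not the literature
  trigonometric correction.
* Element-level property tables cover the common organic elements listed
  in the bundled CSV; others raise a named error.
* No sparse-matrix path; dense O(n²–n³) linear algebra is adequate for
  drug-like molecule sizes.
* QSAR model fitting is out of scope: the package produces feature tables;
  fitting belongs to general-purpose statistics stacks.
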