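# algomd — algebraic topological molecular descriptors

`algomd` computes atom- and bond-based **topological (0–2.5D) molecular
descriptors defined as algebraic forms on molecular pseudographs**, for use
as features in QSAR/QSPR modeling, diversity analysis and high-throughput
virtual screening.  It is a library plus a small CLI aimed at
cheminformaticians who need configurable, reproducible descriptor tables
from MDL MOL/SDF structure files.

## The method

A molecule is modeled as a pseudograph: bond order is edge multiplicity and
diagonal loops can encode aromaticity and/or Lewis lone-pair counts.  From
it two matrix families are built:

* the **atom-based (electronic-density) matrix** `M`, with `m_ij` = bond
  order between atoms `i`,`j` (e.g. 3 for a triple bond) and a configurable
  diagonal;
* the **bond-based (edge-adjacency) matrix** `E`, with `e_vw = 1` when two
  bonds share an atom and an always-zero diagonal.

A descriptor is the bilinear form over the k-th matrix power,

```
b^k(x̄, ȳ) = x̄ᵀ Mᵏ ȳ        k = 0, 1, …, 15
```

with `x̄`,`ȳ` per-atom (or per-bond) property vectors — quadratic indices
take `x̄ = ȳ`, linear indices take `x̄ = 1̄`.  Ten weighting properties are
available (mass M, Van der Waals volume V, polarizability P, Pauling
electronegativity E, Ghose–Crippen logP A, Gasteiger–Marsili charge C,
polar surface area PSA, refractivity R, hardness H, softness S), with bond
weights `w_ij = w_i/δ_i + w_j/δ_j` (δ = multiplicity-weighted degree).

The raw ("non-stochastic", NS) matrix can be normalized to **simple
stochastic** (SS, row sums 1), **double stochastic** (DS, row and column
sums 1, via Sinkhorn–Knopp) or **mutual probability** (MP, grand sum 1)
form.  **Topological cut-offs** keep the diagonal only (SRW), the
off-diagonal only (NSRW) or entries within a shortest-path window
(Lag [p_min, p_max]).  **Local fragments** (H-bond acceptors A, aliphatic
carbons C, donors D, halogens G, terminal methyls M, aromatic carbons P,
heteroatoms X) restrict the matrix by row selection, which makes fragment
indices exactly additive over a disjoint exhaustive partition.

Every total index also decomposes into per-atom/per-bond contributions
(**LOVIs/LOEIs**, jointly LOVEIs), computed in one O(n²) pass; a registry
of 22 **aggregation operators** (norms, means, statistical invariants and
the classical Total-Sum / Kier–Hall / Autocorrelation / Gravitational
algorithms) turns a LOVEI vector into global or local descriptor values.
A **Shannon-entropy module** profiles the information content of computed
descriptor tables.

## Worked example

```python
import algomd as am

mol = am.generate_fixtures("isonicotinic_acid")[0]   # 9 heavy atoms, N1…O9
M   = am.build_ns_atom_matrix(mol, diag_mode="lone_pairs")
x   = am.atomic_property_vector(mol, "E")            # Pauling electronegativity

for k in (0, 1, 2):
    print(k, round(am.quadratic_form(am.matrix_power(M, k), x), 3))
```

prints

```
0 71.924
1 246.755
2 874.18
```

`k = 0` is just `Σ xᵢ²` over the 9 atoms; higher powers weight pairs of
atoms by the number of length-k walks between them, so electron-rich
neighborhoods (the pyridine N, the carboxyl oxygens) dominate.  The same
total splits into atom contributions, which any registered operator
collapses:

```python
L = am.atom_level_lovei(am.matrix_power(M, 2), x, x)
print(round(am.aggregate(L, "TS"), 2),   # 874.18  (= the total above)
      round(am.aggregate(L, "EU"), 2),   # 306.25  (Euclidean norm)
      round(am.aggregate(L, "MX"), 2))   # 170.97  (max: the carbonyl O)
```

From the shell, a full table (here 72 descriptors from a saved XML project)
and its entropy profile:

```bash
algomd compute -i mols.sdf -p project.xml -o out.csv
algomd entropy -i out.csv -o se.csv --threshold 2.0
# 56/72 descriptors (78%) above 2.00 bits (50% of the maximum entropy)
```

`algomd batch -t tasks.xml` runs up to eight independent dataset × project
tasks; `algomd curate` strips salts, duplicates and valence-broken records
with a full report.

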