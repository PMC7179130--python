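# cpgroups

Atom-group additivity prediction of isobaric heat capacities of organic
compounds and ionic liquids at 298.15 K — `Cp(liq, 298)` and `Cp(sol, 298)`
in J/mol/K — plus the full machinery to re-derive the group contributions
from any training set.

## Who this is for

Thermochemists and cheminformaticians who need standard-temperature heat
capacities for compounds that were measured at some other temperature (to
correct temperature-dependent properties such as vaporisation or fusion
enthalpies back to 298.15 K), and who want an auditable, pencil-checkable
prediction rather than a black box.

## The model

Every *backbone* atom (an atom with at least two immediate neighbours,
hydrogens included) is assigned an **atom group**: an atom-type string
(element, hybridisation or aromaticity, formal charge) plus a neighbour
string encoding its immediate environment — e.g. the C1 of ethanol is
`C sp3 / H2CO`. A handful of **special groups** capture effects a local
environment cannot: endocyclic single bonds (lost rotational freedom on
cyclisation), small-ring angle bins (Angle60/90/102), a polyol correction
`(COH)n`, and intramolecular H bridges. Hydroxy oxygens on saturated carbon
are refined into `O(prim)/O(sec)/O(tert)` by the carbon count of the
carbinol carbon, which resolves the systematic primary-vs-tertiary alcohol
error of volume-based estimators. The prediction is the plain sum

```
Cp = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ        [J/mol/K, 298.15 K]
```

with `Aᵢ`/`Bⱼ` the group occurrence counts and `aᵢ`/`bⱼ` the tabulated
contributions (shipped as TSV: 211 liquid-phase rows, 197 solid-phase
rows, ionic-liquid fragments included). Contributions supported by fewer
than three molecules in the underlying regression are kept in the tables
but refused for prediction by default.

The **fitting** side rebuilds those tables from scratch: occurrence-matrix
assembly, normal-equations solution by Gauss–Seidel iteration, 10-fold
cross-validation with pooled held-out predictions (q²), validity marking,
and iterative removal of compounds deviating by more than three
cross-validated standard deviations.

## Worked example

```python
from cpgroups import read_smiles, load_table, predict_cp

table = load_table("liquid")
pred = predict_cp(read_smiles("OCC1CCCCC1", "cyclohexanemethanol"), table)
print(f"Cp(liq,298) = {pred.cp:.2f} J/mol/K")
for key, count, contribution, product in pred.breakdown:
    print(f"  {count:2d} x [{key:22s}] {contribution:8.2f} -> {product:8.2f}")
```

prints

```
Cp(liq,298) = 236.10 J/mol/K
   5 x [C sp3|H2C2           ]    30.06 ->   150.30
   1 x [C sp3|H2CO           ]    73.86 ->    73.86
   1 x [C sp3|HC3            ]    21.11 ->    21.11
   1 x [O(prim)|HC           ]    14.35 ->    14.35
   6 x [Endocyclic bonds     ]    -3.92 ->   -23.52
```

i.e. five ring methylenes, the ring methine, the carbinol methylene, a
primary hydroxy oxygen, and six endocyclic single bonds; the experimental
value is 236.5 J/mol/K. Ion pairs work the same way — the groups of cation
and anion are pooled into one sum:

```bash
cpgroups predict --phase liq --in ionic_liquids.smi --out results.tsv
cpgroups validate            # recompute the bundled fixture set
cpgroups fit --phase liq --train train.tsv --k 10 --seed 7 \
             --out params.tsv --report stats.json
```

`cpgroups validate` recomputes every bundled fixture compound and reports
per-table mean absolute percentage deviations against experiment (3.02%
for the 66-alkanol liquid set).

## Scope and limits

Elements H, B, C, N, O, F, Si, P, S, Cl, Br, I; the structure is taken as
drawn (no tautomer or protomer enumeration); fixed temperature 298.15 K.
Geometry-dependent special groups (Angle102 bins, intramolecular H
bridges) need 3D coordinates — topological fallbacks cover 3- and
4-membered rings only. See `docs/methods.md` for conventions, parameter
semantics and known limitations.
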