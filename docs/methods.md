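# Methods

## Model

The package predicts isobaric heat capacities of the liquid and solid
phase at 298.15 K by atom-group additivity:

    Cp = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ      [J/mol/K]

`Aᵢ` counts occurrences of the i-th atom group, `Bⱼ` of the j-th special
group; `aᵢ`, `bⱼ` are tabulated contributions, one table per phase
(`src/cpgroups/data/cp_liquid.tsv`, 211 rows; `cp_solid.tsv`, 197 rows).
The model assumes strict additivity of local environments; everything
non-local is carried by six special groups (below). Multi-component
records (salts, ion pairs) are one prediction: groups of all components
are pooled. Monatomic counter-ions (halides) have no backbone atom and
contribute zero — the bundled ionic-liquid validation compounds with
bromide/iodide/chloride anions confirm that no implicit halide term is
needed.

## Group notation

A backbone atom (≥2 immediate neighbours, H included) gets an atom-type
string — element, charge, and `sp3/sp2/sp/aromatic` for C and N; `O` (with
the hydroxy refinement below); `S2/S4/S(+)`, `P3/P4/P(+)/P(-)`, `B/B(-)`,
`Si`, `N(-)` — and a neighbour string:

* hydrogens first (`H`, `H2`, …), then heavy neighbours sorted by element
  precedence B < C < N < O < Si < P < S < F < Cl < Br < J (iodine renders
  as `J`), within an element by bond marker: none (single) < `:`
  (aromatic) < `=` (double) < `#` (triple); equal runs collapse with a
  multiplicity digit (`C2`, `F3`, `=O2`);
* a formal charge on any neighbour floats to the end of the element list
  as a single `(+)`/`(-)` suffix: carboxylate C is `CO=O(-)`, nitrate N is
  `O2=O(-)`;
* atom types `N sp3`, `O` and `S2` append `(pi)/(2pi)/(3pi)` counting
  neighbouring C or N atoms that are aromatic or multiply bonded.
  Hypervalent S and P neighbours do not count: a sulfate-ester oxygen is
  `O / CS`, an aryl phosphate oxygen `O / CP(pi)` (the annotation comes
  from the aryl carbon). This distinction is forced by the tables
  themselves and was verified string-by-string against all 408 rows.

### Hydroxy refinement

O bonded to one H and one *saturated* carbon is re-typed by the carbon
count of that carbinol carbon: ≤1 → `O(prim)`, 2 → `O(sec)`, 3 →
`O(tert)`; the neighbour string is then fixed to `HC`. Methanol is folded
into the primary class. O–H on unsaturated or aromatic carbon (acids,
phenols, enols) stays `O / HC(pi)`. The refinement is keyed to the
parameter table: if a table without refined rows is supplied, it is a
no-op.

### Charged heteroaromatics

Pyridinium-type cations need no special handling: the ring nitrogen is
`N(+) aromatic / C:C2` and ortho carbons see `:N(+)`.

1,3-disubstituted imidazolium rings follow a fixed resonance convention
that the contribution tables encode: the positive charge is placed on C2
(`C(+) aromatic / H:N2`), both nitrogens take the dedicated
`N aromatic / C2:C(+)` type, C4/C5 are perceived as localised sp2
carbons (`C sp2 / H=CN`), and substituents on the ring nitrogens see a
*neutral* N (`C sp3 / H2CN`, `H3N`). Under this convention every
imidazolium ionic liquid in the bundled validation set reproduces its
printed prediction to ≤0.2 J/mol/K (e.g. EMIM-NTf2: 506.69 vs 506.70;
EMIM-BF4: 307.60 exactly); treating C4/C5 as aromatic and the alkyls as
seeing N(+) instead leaves a systematic ≈100 J/mol/K gap per cation,
which is how the convention was identified.

Other five-membered heteroaromatics with a lone-pair heteroatom (pyrrole-,
furan-, thiophene-type, i.e. both kekulé ring bonds single) are perceived
on their kekulé structure: the heteroatom becomes sp3/divalent with pi
annotations, ring carbons sp2. Bonds shared with a fused six-membered
aromatic ring stay aromatic. Indole-containing fixtures (tryptophan)
validate this choice; a fully aromatic treatment has no table rows for the
pyrrole N at all. Endocyclic-bond counting ignores this localisation (see
below).

## Special groups

| key | counting rule | liquid bⱼ | solid bⱼ |
|---|---|---|---|
| Endocyclic bonds | single, non-aromatic ring bonds; fused bonds once; kekulé-localised heteroaromatic rings do **not** count | −3.92 | −1.44 |
| Angle60 / Angle90 / Angle102 | with 3D coordinates: for each atom, every pair of ring bonds is binned by angle θ: θ<62°, 62–90°, 90–102° (the 2° slack absorbs ideal-geometry jitter at 60°); without coordinates: each 3-ring adds 3×Angle60, each 4-ring 4×Angle90, Angle102 stays 0 | 4.13 / 1.70 / — | 0.97 / 0.31 / 2.16 |
| (COH)n | 1 when the molecule has >1 C–O–H group (`cohn_mode="once"`, default); `per_oh` counts each OH | −27.73 | 3.46 |
| H/H Acceptor | geometry only: H on O/N/S within 2.5 Å of an O/N/F acceptor ≥3 bonds away | −21.43 | 1.19 |

A nonzero Angle102 count against the liquid table (which has no such row)
is ignored with a warning.

Norbornane-type skeletons make the Angle102 geometry dependence concrete:
the printed solid-phase predictions for norbornane and borneol/isoborneol
imply eleven ring-bond-pair angles in the 90–102° bin (exactly the number
of ring-bond pairs in a bicyclo[2.2.1] cage), which a topological fallback
cannot supply. Such fixtures carry a `geometry` flag and are excluded from
strict regression; `cpgroups.chem_model.embed_3d` (ETKDG + MMFF) can
attach an approximate conformer, but force-field angles near the 102° bin
edge are not reliable enough to assert printed values against.

### Polyol caveat

The diol validation series pins the `(COH)n` solid correction to a single
occurrence per molecule (1,6- through 1,16-diols reproduce to ≤0.2
J/mol/K with `once` mode). Polyols with >2 OH (erythritol, xylitol,
sorbitol, inositol, …) reproduce under *neither* `once` nor `per_oh`;
their printed values are most consistent with an occurrence count of
(n_OH − 1) plus geometry-dependent H-bridge terms, but the printed data
cannot pin this down (sorbitol and dulcitol have identical group multisets
yet different printed predictions — only a geometric special can separate
them). These fixtures carry a `polyol` flag and are excluded from strict
regression.

## Prediction policy

A group absent from the table makes the result *not computable* (reported,
not raised): bounded applicability is intrinsic to group contribution.
Rows supported by fewer than 3 distinct molecules are invalid for
prediction; `allow_invalid_groups=True` overrides. Amino acids are
predicted from the structure as drawn — the zwitterion question is left to
the caller.

## Fitting

* **Design matrix**: M compounds × N observed group keys, integer
  occurrence counts; per-group distinct-molecule support is tracked.
* **Solver**: normal equations (GᵀG)x = Gᵀy, solved by Gauss–Seidel
  sweeps (matrix form, forward substitution with the lower triangle —
  identical to the coordinate-wise update). GᵀG of a full-column-rank
  count matrix is symmetric positive definite, for which the iteration
  converges to the least-squares solution. Stopping uses a geometric
  error estimate Δ·q/(1−q) (q the observed contraction factor) rather
  than the raw step size, which understates the error badly for nearly
  collinear columns; default tolerance 1e-9, cap 200 000 sweeps.
* **Cross-validation**: seeded shuffle into k=10 near-equal folds; every
  compound is held out exactly once. Held-out compounds needing a group
  with <3 distinct supporting molecules in the training folds are excluded
  from the CV pool (this reproduces the "fitted n > cross-validated n"
  pattern of group-contribution regressions).
* **Outlier loop**: fit → CV → remove *all* compounds whose training
  residual exceeds 3× the cross-validated standard deviation → repeat to
  convergence. The limit has an absolute floor of 1e-6 J/mol/K so that an
  essentially exact fit does not flag solver-tolerance noise.
* **Statistics**: r²/q² are squared Pearson correlations (the 1−SSE/SST
  variant is emitted alongside as `r2_sse`); `avg_dev` is mean |Δ|;
  `std_dev` uses n−1; MAPD = 100/n·Σ|Δ|/exp. Headline statistics are
  computed only over compounds all of whose groups are valid.

## Synthetic generator

`SyntheticSpec` defaults: the 30 best-supported valid liquid-table groups
with their shipped contributions as ground truth, 500 molecules, noise
σ = 8 J/mol/K (the order of the liquid-phase residual SD), 2–6 distinct
groups per molecule with counts 1–4, full column rank and ≥3-molecule
support enforced, fully deterministic under the seed. It emulates the
*structure* of a real training set (sparse shared integer counts), not its
chemistry: chemically induced collinearity between groups and
heteroscedastic experimental error are absent, so passing recovery tests
demonstrate solver and bookkeeping correctness, not robustness to real
data pathologies.

## Numerical / degenerate-input choices

* Gauss–Seidel zero diagonal (all-zero column) and non-convergence raise
  with the offending column / last residual norm.
* Pearson r² of a zero-variance vector is defined as 1.0 for an exact
  match and 0.0 otherwise.
* MAPD refuses zero experimental values.
* Fold sizes differ by at most one; the fold seed is recorded in the
  `FitResult`.
* Angle binning clips cosines to [−1, 1] before `arccos`.

## Validation fixtures

`cpgroups.fixtures.build_fixture_set()` ships 191 curated records
(name, SMILES, phase, printed group-additivity value, experimental value):
66 liquid alkanols, 8 alkanes/cycloalkanes (liquid), 31 solid alkanols,
18 solid alkanes/cycloalkanes, 21 zwitterionic amino acids, and 47 ionic
liquids spanning imidazolium, pyridinium, pyrrolidinium, piperidinium,
ammonium, phosphonium, sulfonium, isoquinolinium and protic
hydroxyethylammonium cations with all major anion families. 177 records
are *strict* (reproduce their printed value within max(0.25 J/mol/K,
0.5%), covering two-decimal rounding of the tabulated contributions); 14
carry `polyol`/`geometry` flags for the reasons above. Structures were
curated from compound names; stereochemistry is irrelevant to the 2D
perception and is dropped.

## Known limitations

* Element scope H, B, C, N, O, F, Si, P, S, Cl, Br, I; no radicals or
  coordination complexes.
* Fixed 298.15 K; no temperature dependence, no gas phase.
* The structure is taken as drawn: thiocyanate must be drawn as S=C=[N−]
  to match the tabulated `=N=S(-)` group; amino-acid protomers are the
  caller's choice.
* Geometry-dependent specials silently count zero without coordinates
  (logged); predictions for strained cages and H-bridged polyols are then
  systematically off by the corresponding terms.
* Full-scale re-derivation of the shipped tables requires the original
  ~1200/800-compound experimental collections, which are not bundled; the
  fitting machinery is validated on synthetic data and small real subsets
  instead.
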