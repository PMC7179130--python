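"""Atom-group perception in the contribution tables' notation.

Every *backbone* atom (an atom bound to at least two immediate neighbours,
hydrogens included) is assigned an atom-type string (element, hybridisation
or aromaticity, formal charge) and a neighbour string (hydrogen count first,
then heavy neighbours with bond-order markers, element multiplicities,
floating charge suffixes and pi annotations). Terminal atoms — halogens,
carbonyl oxygens, nitrile nitrogens, hydrogens — appear only inside
neighbour strings.

Notation rules implemented here (inferred from the shipped tables and
verified string-by-string against them):

* neighbour order: ``Hn`` first, then heavy neighbours sorted by element
  precedence B < C < N < O < Si < P < S < F < Cl < Br < J and, within one
  element, by bond marker (single < ``:`` aromatic < ``=`` double < ``#``
  triple); equal (element, marker) runs collapse to a multiplicity digit
  (``C2``, ``F3``, ``=O2``);
* iodine renders as ``J`` in neighbour strings (table convention) while the
  element model keeps ``I``;
* a charge on any neighbour floats to the end of the element list as one
  ``(+)`` / ``(-)`` suffix (``CO=O(-)`` for carboxylate, ``O2=O(-)`` for
  nitrate), before any pi annotation;
* for sp3 N, divalent S and unrefined hydroxy/ether O atom types, a trailing
  ``(pi)``/``(2pi)``/``(3pi)`` counts neighbouring C or N atoms that are
  aromatic or multiply bonded (hypervalent S and P neighbours do not count:
  the tables write ``O CS`` for sulfate esters but ``O C2(pi)`` for
  carboxylate esters);
* 1,3-dialkylimidazolium rings follow the tables' fixed resonance
  convention: the positive charge sits on C2 (``C(+) aromatic / H:N2``),
  both ring nitrogens are the special ``N aromatic / C2:C(+)`` type, C4/C5
  are localised sp2 carbons (``C sp2 / H=CN``) and substituents on the ring
  nitrogens see a neutral N;
* other five-membered heteroaromatics (pyrrole-, furan-, thiophene-type)
  are perceived on their kekulé structure: the lone-pair heteroatom becomes
  an sp3/divalent type with pi annotations and the ring carbons sp2.

The hydroxy-oxygen refinement O(prim)/O(sec)/O(tert) keyed to the carbinol
carbon's carbon count, and the special-group counters of the method
(endocyclic single bonds, small-ring angle bins, the polyol ``(COH)n``
flag, intramolecular H bridges) live here as well.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_model import Molecule

log = logging.getLogger(__name__)

# special-group canonical keys (shared with the contribution tables)
ENDOCYCLIC = "Endocyclic bonds"
ANGLE60 = "Angle60"
ANGLE90 = "Angle90"
ANGLE102 = "Angle102"
COHN = "(COH)n"
HH_ACCEPTOR = "H/H Acceptor"
SPECIAL_KEYS = (ENDOCYCLIC, ANGLE60, ANGLE90, ANGLE102, COHN, HH_ACCEPTOR)

_ELEMENT_ORDER = {
    "B": 0, "C": 1, "N": 2, "O": 3, "Si": 4, "P": 5,
    "S": 6, "F": 7, "Cl": 8, "Br": 9, "J": 10,
}
_MARKER_ORDER = {"": 0, ":": 1, "=": 2, "#": 3}
_MARKER_BY_ORDER = {1.0: "", 1.5: ":", 2.0: "=", 3.0: "#"}


class PerceptionError(ValueError):
    """Unsupported atom environment: no table-constructible group exists."""


@dataclass(frozen=True)
class AtomGroup:
    """(atom type, neighbours) pair — the unit of the additivity model."""

    atom_type: str
    neighbours: str

    @property
    def key(self) -> str:
        return f"{self.atom_type}|{self.neighbours}"


@dataclass
class PerceptionConfig:
    """Tunable conventions of the perception step.

    cohn_mode: how the polyol special counts — "once" (a single flag
        occurrence when the molecule has >1 OH, the default) or "per_oh"
        (one occurrence per OH group).
    hh_max_distance: H...acceptor cutoff in Angstrom for intramolecular
        hydrogen bridges (geometry-dependent; 0 bridges without coordinates).
    hh_min_bond_separation: minimum bond-path length between donor heavy
        atom and acceptor.
    """

    cohn_mode: str = "once"
    hh_max_distance: float = 2.5
    hh_min_bond_separation: int = 3

    def __post_init__(self):
        if self.cohn_mode not in ("once", "per_oh"):
            raise ValueError(f"cohn_mode must be 'once' or 'per_oh', got {self.cohn_mode!r}")


@dataclass
class GroupCountVector:
    """Counts A_i of atom groups and B_j of special groups for one record."""

    atom_group_counts: Counter = field(default_factory=Counter)
    special_counts: Counter = field(default_factory=Counter)

    @property
    def n_backbone_atoms(self) -> int:
        return sum(self.atom_group_counts.values())

    def all_counts(self) -> dict[str, int]:
        out = dict(self.atom_group_counts)
        out.update({k: v for k, v in self.special_counts.items() if v})
        return out

    def __add__(self, other: "GroupCountVector") -> "GroupCountVector":
        return GroupCountVector(
            self.atom_group_counts + other.atom_group_counts,
            self.special_counts + other.special_counts,
        )


# ---------------------------------------------------------------------------
# effective structure view (kekulé localisation + imidazolium convention)
# ---------------------------------------------------------------------------

class _View:
    """Effective aromaticity/bond-order/charge view of an RDKit mol."""

    def __init__(self, mol: Molecule):
        self.mol = mol
        rd = mol.to_rdkit()
        self.rd = rd
        kek = Chem.Mol(rd)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        self.n = rd.GetNumAtoms()
        self.atom_aromatic = [a.GetIsAromatic() for a in rd.GetAtoms()]
        self.charge = [a.GetFormalCharge() for a in rd.GetAtoms()]
        # effective numeric order per bond (1/1.5/2/3); aromatic flag per bond
        self.bond_order: dict[tuple[int, int], float] = {}
        self.bond_aromatic: dict[tuple[int, int], bool] = {}
        self.kek_order: dict[tuple[int, int], float] = {}
        for b in rd.GetBonds():
            key = self._bkey(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            self.bond_aromatic[key] = b.GetIsAromatic()
            self.bond_order[key] = 1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()
        for b in kek.GetBonds():
            key = self._bkey(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            self.kek_order[key] = b.GetBondTypeAsDouble()
        self.overrides: dict[int, AtomGroup] = {}
        self.imidazolium_atoms: set[int] = set()
        self._apply_imidazolium_convention()
        self._localize_five_ring_heteroaromatics()

    @staticmethod
    def _bkey(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def order(self, i: int, j: int) -> float:
        return self.bond_order[self._bkey(i, j)]

    def is_aromatic_bond(self, i: int, j: int) -> bool:
        return self.bond_aromatic[self._bkey(i, j)]

    def heavy_neighbors(self, i: int) -> list[int]:
        return [a.GetIdx() for a in self.rd.GetAtomWithIdx(i).GetNeighbors()]

    def n_hydrogens(self, i: int) -> int:
        return self.rd.GetAtomWithIdx(i).GetTotalNumHs()

    def degree(self, i: int) -> int:
        return len(self.heavy_neighbors(i)) + self.n_hydrogens(i)

    def multiple_bond_counts(self, i: int) -> tuple[int, int]:
        """(#double, #triple) effective non-aromatic multiple bonds at atom i."""
        d = t = 0
        for j in self.heavy_neighbors(i):
            o = self.order(i, j)
            if o == 2.0:
                d += 1
            elif o == 3.0:
                t += 1
        return d, t

    def is_unsaturated(self, i: int) -> bool:
        """Aromatic or carrying at least one double/triple bond."""
        if self.atom_aromatic[i]:
            return True
        d, t = self.multiple_bond_counts(i)
        return d + t > 0

    # -- charged-heteroaromatic normalisation ------------------------------
    def _apply_imidazolium_convention(self) -> None:
        ri = self.rd.GetRingInfo()
        for ring in ri.AtomRings():
            if len(ring) != 5:
                continue
            atoms = [self.rd.GetAtomWithIdx(i) for i in ring]
            if not all(a.GetIsAromatic() for a in atoms):
                continue
            syms = sorted(a.GetSymbol() for a in atoms)
            if syms != ["C", "C", "C", "N", "N"]:
                continue
            n_idx = [a.GetIdx() for a in atoms if a.GetSymbol() == "N"]
            if sum(self.charge[i] for i in ring) != 1:
                continue
            # both N trisubstituted (incl. H) -> imidazolium-type cation
            if any(self.degree(i) != 3 for i in n_idx):
                continue
            c2 = [
                a.GetIdx() for a in atoms
                if a.GetSymbol() == "C"
                and set(n_idx) <= {nb.GetIdx() for nb in a.GetNeighbors()}
            ]
            if len(c2) != 1:
                continue  # N adjacent (pyrazolium-type): not this convention
            c2 = c2[0]
            c45 = [i for i in ring if i != c2 and i not in n_idx]
            # fixed resonance convention: + on C2, both N neutral
            for i in n_idx:
                self.charge[i] = 0
            self.charge[c2] = 1
            self.imidazolium_atoms.update(ring)
            self.overrides[c2] = AtomGroup(
                "C(+) aromatic",
                self._assemble(
                    self.n_hydrogens(c2),
                    [
                        ("N", ":", 0) if j in n_idx
                        else (_render(self.rd.GetAtomWithIdx(j).GetSymbol()), "", self.charge[j])
                        for j in self.heavy_neighbors(c2)
                    ],
                ),
            )
            for i in n_idx:
                entries = []
                for j in self.heavy_neighbors(i):
                    if j == c2:
                        entries.append(("C", ":", 1))
                    else:  # ring C4/C5 and exocyclic substituents: plain single
                        entries.append(
                            (_render(self.rd.GetAtomWithIdx(j).GetSymbol()), "", self.charge[j])
                        )
                self.overrides[i] = AtomGroup(
                    "N aromatic", self._assemble(self.n_hydrogens(i), entries)
                )
            for i in c45:
                other = [j for j in c45 if j != i][0]
                entries = []
                for j in self.heavy_neighbors(i):
                    if j == other:
                        entries.append(("C", "=", 0))
                    elif j in n_idx:
                        entries.append(("N", "", 0))
                    else:
                        entries.append(
                            (_render(self.rd.GetAtomWithIdx(j).GetSymbol()), "", self.charge[j])
                        )
                self.overrides[i] = AtomGroup(
                    "C sp2", self._assemble(self.n_hydrogens(i), entries)
                )

    # -- pyrrole/furan/thiophene localisation ------------------------------
    def _localize_five_ring_heteroaromatics(self) -> None:
        ri = self.rd.GetRingInfo()
        rings = ri.AtomRings()
        ring_aromatic = [
            all(self.rd.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
            for ring in rings
        ]
        to_localize = []
        for ridx, ring in enumerate(rings):
            if len(ring) != 5 or not ring_aromatic[ridx]:
                continue
            if set(ring) & self.imidazolium_atoms:
                continue
            ring_set = set(ring)
            pyrrole_type = False
            for i in ring:
                sym = self.rd.GetAtomWithIdx(i).GetSymbol()
                if sym not in ("N", "O", "S"):
                    continue
                ring_bonds = [j for j in self.heavy_neighbors(i) if j in ring_set]
                if all(self.kek_order[self._bkey(i, j)] == 1.0 for j in ring_bonds):
                    pyrrole_type = True
                    break
            if pyrrole_type:
                to_localize.append(ridx)
        if not to_localize:
            return
        localized = set(to_localize)
        for ridx in to_localize:
            ring = rings[ridx]
            ring_set = set(ring)
            for i in ring:
                # atom stays aromatic if it sits in another, kept-aromatic ring
                in_other = any(
                    ridx2 != ridx and i in rings[ridx2] and ring_aromatic[ridx2]
                    and ridx2 not in localized
                    for ridx2 in range(len(rings))
                )
                if not in_other:
                    self.atom_aromatic[i] = False
            for i in ring:
                for j in self.heavy_neighbors(i):
                    if j not in ring_set or j < i:
                        continue
                    key = self._bkey(i, j)
                    shared = any(
                        ridx2 != ridx and i in rings[ridx2] and j in rings[ridx2]
                        and ring_aromatic[ridx2] and ridx2 not in localized
                        for ridx2 in range(len(rings))
                    )
                    if not shared:
                        self.bond_aromatic[key] = False
                        self.bond_order[key] = self.kek_order[key]

    # -- string assembly ----------------------------------------------------
    @staticmethod
    def _assemble(n_h: int, entries: Sequence[tuple[str, str, int]]) -> str:
        """Build a neighbour string from (element, marker, charge) entries."""
        for e, _, _ in entries:
            if e not in _ELEMENT_ORDER:
                raise PerceptionError(f"element {e!r} cannot appear in a neighbour string")
        parts = []
        if n_h == 1:
            parts.append("H")
        elif n_h > 1:
            parts.append(f"H{n_h}")
        ordered = sorted(entries, key=lambda t: (_ELEMENT_ORDER[t[0]], _MARKER_ORDER[t[1]]))
        i = 0
        while i < len(ordered):
            elem, marker, _ = ordered[i]
            k = i
            while k < len(ordered) and ordered[k][0] == elem and ordered[k][1] == marker:
                k += 1
            mult = k - i
            parts.append(f"{marker}{elem}{mult if mult > 1 else ''}")
            i = k
        if any(c > 0 for _, _, c in entries):
            parts.append("(+)")
        if any(c < 0 for _, _, c in entries):
            parts.append("(-)")
        return "".join(parts)


def _render(symbol: str) -> str:
    return "J" if symbol == "I" else symbol


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------

def _charge_suffix(q: int) -> str:
    return "(+)" if q > 0 else "(-)" if q < 0 else ""


def _hybridization(view: _View, i: int) -> str:
    d, t = view.multiple_bond_counts(i)
    if t >= 1 or d >= 2:
        return "sp"
    if d == 1:
        return "sp2"
    return "sp3"


def _atom_type(view: _View, i: int) -> str:
    atom = view.rd.GetAtomWithIdx(i)
    sym = atom.GetSymbol()
    q = view.charge[i]
    arom = view.atom_aromatic[i]
    if sym == "C":
        if arom:
            return f"C{_charge_suffix(q)} aromatic"
        return f"C{_charge_suffix(q)} {_hybridization(view, i)}"
    if sym == "N":
        if q < 0:
            return "N(-)"
        if arom:
            return f"N{_charge_suffix(q)} aromatic"
        return f"N{_charge_suffix(q)} {_hybridization(view, i)}"
    if sym == "O":
        if q != 0:
            raise PerceptionError(f"unsupported atom environment: charged backbone O (atom {i})")
        return "O"
    if sym == "S":
        if q > 0:
            return "S(+)"
        if q < 0:
            raise PerceptionError(f"unsupported atom environment: S(-) backbone (atom {i})")
        d, t = view.multiple_bond_counts(i)
        return "S4" if d + t > 0 else "S2"
    if sym == "P":
        if q > 0:
            return "P(+)"
        if q < 0:
            return "P(-)"
        d, t = view.multiple_bond_counts(i)
        return "P4" if d + t > 0 else "P3"
    if sym == "B":
        return "B(-)" if q < 0 else "B"
    if sym == "Si":
        return "Si"
    raise PerceptionError(
        f"unsupported atom environment: {sym} (atom {i}) cannot be a backbone atom"
    )


_PI_ANNOTATED_TYPES = ("N sp3", "O", "S2")


def _pi_annotation(view: _View, i: int, atom_type: str) -> str:
    """Trailing (pi)/(2pi)/(3pi) for sp3 N, divalent S and ether/hydroxy O."""
    if atom_type not in _PI_ANNOTATED_TYPES:
        return ""
    u = 0
    for j in view.heavy_neighbors(i):
        sym = view.rd.GetAtomWithIdx(j).GetSymbol()
        if view.atom_aromatic[j]:
            u += 1
        elif sym in ("C", "N") and view.is_unsaturated(j):
            u += 1
    if u == 0:
        return ""
    return "(pi)" if u == 1 else f"({u}pi)"


def _neighbour_string(view: _View, i: int, atom_type: str) -> str:
    entries = []
    for j in view.heavy_neighbors(i):
        sym = _render(view.rd.GetAtomWithIdx(j).GetSymbol())
        o = view.order(i, j)
        if view.is_aromatic_bond(i, j):
            marker = ":"
        else:
            marker = _MARKER_BY_ORDER.get(o)
            if marker is None or marker == ":":
                marker = {1.0: "", 2.0: "=", 3.0: "#"}.get(round(o), "")
        entries.append((sym, marker, view.charge[j]))
    return view._assemble(view.n_hydrogens(i), entries) + _pi_annotation(view, i, atom_type)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def assign_atom_groups(mol: Molecule) -> list[tuple[int, AtomGroup]]:
    """Assign a (atom type, neighbours) group to every backbone atom.

    Returns (atom_index, group) pairs; atoms with fewer than two immediate
    neighbours (hydrogens count) are terminal and receive no group.
    """
    view = _View(mol)
    out: list[tuple[int, AtomGroup]] = []
    for i in range(view.n):
        if view.degree(i) < 2:
            continue
        if i in view.overrides:
            out.append((i, view.overrides[i]))
            continue
        at = _atom_type(view, i)
        out.append((i, AtomGroup(at, _neighbour_string(view, i, at))))
    return out


def refine_hydroxy_groups(
    groups: Sequence[tuple[int, AtomGroup]],
    mol: Molecule,
    table_keys: Optional[set[str]] = None,
) -> list[tuple[int, AtomGroup]]:
    """Redefine hydroxy O on saturated carbon into O(prim)/O(sec)/O(tert).

    The class is keyed to the number of carbon atoms on the carbinol carbon
    (0 or 1 -> primary, 2 -> secondary, 3 -> tertiary); the neighbour string
    of a refined oxygen is fixed to "HC". O-H on unsaturated carbon
    (phenols, acids, enols) keeps ("O", "HC(pi)"). A no-op for oxygens whose
    refined type is absent from ``table_keys`` (when given), mirroring the
    rule that the parameter table's content decides which refinements are in
    force.
    """
    view = _View(mol)
    out = []
    for i, g in groups:
        if g.atom_type != "O" or view.n_hydrogens(i) != 1:
            out.append((i, g))
            continue
        heavy = view.heavy_neighbors(i)
        if len(heavy) != 1:
            out.append((i, g))
            continue
        c = heavy[0]
        c_atom = view.rd.GetAtomWithIdx(c)
        if c_atom.GetSymbol() != "C" or view.atom_aromatic[c] or view.is_unsaturated(c):
            out.append((i, g))
            continue
        n_carbons = sum(
            1 for j in view.heavy_neighbors(c)
            if j != i and view.rd.GetAtomWithIdx(j).GetSymbol() == "C"
        )
        refined = {0: "O(prim)", 1: "O(prim)", 2: "O(sec)", 3: "O(tert)"}[n_carbons]
        if table_keys is not None and f"{refined}|HC" not in table_keys:
            out.append((i, g))
            continue
        out.append((i, AtomGroup(refined, "HC")))
    return out


def _count_oh_groups(view: _View) -> int:
    """C-O-H oxygens (alcohols, phenols, carboxylic OH)."""
    n = 0
    for i in range(view.n):
        a = view.rd.GetAtomWithIdx(i)
        if a.GetSymbol() != "O" or view.n_hydrogens(i) < 1:
            continue
        if any(view.rd.GetAtomWithIdx(j).GetSymbol() == "C" for j in view.heavy_neighbors(i)):
            n += 1
    return n


def _angle_specials_from_geometry(view: _View) -> Counter:
    conf_mol = view.rd
    conf = conf_mol.GetConformer()
    pos = conf.GetPositions()
    counts: Counter = Counter()
    for i in range(view.n):
        ring_nb = [
            j for j in view.heavy_neighbors(i)
            if conf_mol.GetBondBetweenAtoms(i, j).IsInRing()
        ]
        for a in range(len(ring_nb)):
            for b in range(a + 1, len(ring_nb)):
                v1 = pos[ring_nb[a]] - pos[i]
                v2 = pos[ring_nb[b]] - pos[i]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if theta < 62.0:
                    counts[ANGLE60] += 1
                elif theta < 90.0:
                    counts[ANGLE90] += 1
                elif theta <= 102.0:
                    counts[ANGLE102] += 1
    return counts


def _angle_specials_topological(view: _View) -> Counter:
    """Without geometry: 3-rings force 60-degree angles, 4-rings 90-degree."""
    counts: Counter = Counter()
    for ring in view.rd.GetRingInfo().AtomRings():
        if len(ring) == 3:
            counts[ANGLE60] += 3
        elif len(ring) == 4:
            counts[ANGLE90] += 4
    return counts


def _hh_acceptor_count(view: _View, mol: Molecule, config: PerceptionConfig) -> int:
    if not mol.has_coords or mol.n_heavy_atoms == 0:
        return 0
    rdh = Chem.AddHs(Chem.Mol(view.rd), addCoords=True)
    pos = rdh.GetConformer().GetPositions()
    dmat = Chem.GetDistanceMatrix(rdh)  # topological (bond-count) distances
    donors = []  # (H index, heavy donor index)
    acceptors = []
    for a in rdh.GetAtoms():
        sym = a.GetSymbol()
        if sym in ("O", "N", "F"):
            acceptors.append(a.GetIdx())
        if sym in ("O", "N", "S"):
            for nb in a.GetNeighbors():
                if nb.GetSymbol() == "H":
                    donors.append((nb.GetIdx(), a.GetIdx()))
    n = 0
    for h, d in donors:
        for acc in acceptors:
            if acc == d:
                continue
            if dmat[d][acc] < config.hh_min_bond_separation:
                continue
            if np.linalg.norm(pos[h] - pos[acc]) < config.hh_max_distance:
                n += 1
    return n


def count_special_groups(
    mol: Molecule, config: Optional[PerceptionConfig] = None
) -> Counter:
    """Count the method's special groups B_j for one record.

    EndocyclicBonds counts single (non-aromatic) ring bonds, each fused-ring
    shared bond once. Angle60/90/102 bin ring-internal bond angles when 3D
    coordinates exist; the topological fallback charges 3-membered rings
    with three Angle60 and 4-membered rings with four Angle90 (those angles
    are forced by topology) and leaves Angle102 at zero. The (COH)n flag is
    set for molecules with more than one OH group; H/H-Acceptor bridges are
    geometry-only.
    """
    config = config or PerceptionConfig()
    view = _View(mol)
    counts: Counter = Counter({k: 0 for k in SPECIAL_KEYS})
    # original (pre-localisation) aromaticity decides: kekulé single bonds
    # inside de-aromatised heterocycles are NOT endocyclic
    for b in view.rd.GetBonds():
        if b.IsInRing() and not b.GetIsAromatic() \
                and b.GetBondType() == Chem.BondType.SINGLE:
            counts[ENDOCYCLIC] += 1
    if mol.has_coords and mol.n_heavy_atoms > 0:
        counts.update(_angle_specials_from_geometry(view))
    else:
        counts.update(_angle_specials_topological(view))
    n_oh = _count_oh_groups(view)
    if n_oh > 1:
        counts[COHN] = n_oh if config.cohn_mode == "per_oh" else 1
    hh = _hh_acceptor_count(view, mol, config)
    if hh == 0 and not mol.has_coords:
        log.debug("%s: no coordinates, H/H-Acceptor count is 0", mol.name)
    counts[HH_ACCEPTOR] = hh
    return counts


def perceive(
    mol: Molecule,
    config: Optional[PerceptionConfig] = None,
    table_keys: Optional[set[str]] = None,
) -> GroupCountVector:
    """Full perception: atom groups, hydroxy refinement, special groups."""
    groups = refine_hydroxy_groups(assign_atom_groups(mol), mol, table_keys)
    gcv = GroupCountVector()
    for _, g in groups:
        gcv.atom_group_counts[g.key] += 1
    gcv.special_counts.update(count_special_groups(mol, config))
    return gcv


def debug_table(mol: Molecule) -> str:
    """Per-atom TSV dump (index, element, atom type, neighbour string)."""
    groups = dict(refine_hydroxy_groups(assign_atom_groups(mol), mol))
    lines = ["atom\telement\tatom_type\tneighbours"]
    for a in mol.atoms:
        g = groups.get(a.index)
        lines.append(
            f"{a.index}\t{a.element}\t{g.atom_type if g else '-'}\t"
            f"{g.neighbours if g else '(terminal)'}"
        )
    return "\n".join(lines)
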