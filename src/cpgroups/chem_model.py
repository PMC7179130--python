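"""Molecular structure model and SMILES/SDF I/O.

The perception substrate for the group-additivity heat-capacity method:
elements, bond orders, aromaticity, formal charges, ring membership,
hydrogen counts and (optional) 3D coordinates. Parsing, aromaticity and
ring perception are delegated to RDKit; this module exposes a small stable
data model on top of it so that the rest of the package never touches
RDKit objects directly.

Supported elements are those of the underlying method: H, B, C, N, O, F,
Si, P, S, Cl, Br, I. Disconnected records (salts, ion pairs) are kept as
one :class:`Molecule`; the predictor pools the groups of all components.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.warning")

log = logging.getLogger(__name__)

#: Elements the group-additivity method is defined for.
SUPPORTED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)


class BondOrder(Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


class UnsupportedElementError(ValueError):
    """Raised when a structure contains an element outside the method's scope."""


class ParseError(ValueError):
    """Raised for unparseable SMILES or SDF records."""


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    aromatic: bool
    n_hydrogens: int          # implicit + explicit H
    index: int
    coords: Optional[np.ndarray] = None

    @property
    def has_coords(self) -> bool:
        return self.coords is not None


@dataclass(frozen=True)
class Bond:
    begin: int
    end: int
    order: BondOrder
    in_ring: bool

    def other(self, idx: int) -> int:
        return self.end if idx == self.begin else self.begin


@dataclass
class Molecule:
    """A parsed structure (possibly multi-component, e.g. an ion pair)."""

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    _rdkit: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "Molecule":
        if mol is None:
            raise ParseError("cannot build Molecule from None")
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        atoms = []
        for a in mol.GetAtoms():
            sym = a.GetSymbol()
            if sym not in SUPPORTED_ELEMENTS:
                raise UnsupportedElementError(
                    f"element {sym!r} (atom {a.GetIdx()}) is outside the "
                    f"supported set {sorted(SUPPORTED_ELEMENTS)}"
                )
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(a.GetIdx())
                xyz = np.array([p.x, p.y, p.z])
            atoms.append(
                Atom(
                    element=sym,
                    formal_charge=a.GetFormalCharge(),
                    aromatic=a.GetIsAromatic(),
                    n_hydrogens=a.GetTotalNumHs(),
                    index=a.GetIdx(),
                    coords=xyz,
                )
            )
        order_map = {
            Chem.BondType.SINGLE: BondOrder.SINGLE,
            Chem.BondType.DOUBLE: BondOrder.DOUBLE,
            Chem.BondType.TRIPLE: BondOrder.TRIPLE,
            Chem.BondType.AROMATIC: BondOrder.AROMATIC,
        }
        bonds = []
        for b in mol.GetBonds():
            try:
                order = order_map[b.GetBondType()]
            except KeyError:
                raise ParseError(
                    f"unsupported bond type {b.GetBondType()} between atoms "
                    f"{b.GetBeginAtomIdx()}-{b.GetEndAtomIdx()}"
                )
            bonds.append(
                Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, b.IsInRing())
            )
        return cls(atoms=atoms, bonds=bonds, name=name, _rdkit=mol)

    def to_rdkit(self) -> Chem.Mol:
        if self._rdkit is None:
            raise ValueError("Molecule was not built from an RDKit mol")
        return self._rdkit

    # -- derived properties ------------------------------------------------
    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    @property
    def has_coords(self) -> bool:
        return all(a.has_coords for a in self.atoms)

    @property
    def components(self) -> int:
        """Number of connected components (flood fill over the bond graph)."""
        n = len(self.atoms)
        if n == 0:
            return 0
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for b in self.bonds:
            adj[b.begin].append(b.end)
            adj[b.end].append(b.begin)
        seen: set[int] = set()
        count = 0
        for start in range(n):
            if start in seen:
                continue
            count += 1
            stack = [start]
            while stack:
                i = stack.pop()
                if i in seen:
                    continue
                seen.add(i)
                stack.extend(j for j in adj[i] if j not in seen)
        return count

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.begin == idx:
                out.append(b.end)
            elif b.end == idx:
                out.append(b.begin)
        return out

    def degree(self, idx: int) -> int:
        """Number of immediate neighbours, hydrogens included."""
        return len(self.neighbors(idx)) + self.atoms[idx].n_hydrogens


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_smiles(smiles: str, name: str = "") -> Molecule:
    """Parse one (possibly multi-component, '.'-separated) SMILES string.

    Aromaticity is perceived by RDKit; implicit hydrogens are counted.
    No coordinates are attached, so geometry-dependent special groups fall
    back to their topological estimates.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return Molecule.from_rdkit(mol, name=name or smiles)


def iter_sdf(path: str | Path) -> Iterator[tuple[int, Molecule | Exception]]:
    """Yield (record_index, Molecule-or-error) for every record of an SDF file.

    Malformed records yield the exception instead of aborting the file.
    Explicit hydrogens are folded into per-atom H counts; 3D coordinates and
    charge blocks are preserved.
    """
    if Path(path).stat().st_size == 0:
        return
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield i, ParseError(f"malformed SDF record {i} in {path}")
            continue
        try:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"
            yield i, Molecule.from_rdkit(mol, name=name)
        except (ParseError, UnsupportedElementError) as exc:
            yield i, exc


def read_sdf(path: str | Path, strict: bool = False) -> list[Molecule]:
    """Read all parseable records of an MDL SDF/MOL V2000 file.

    With ``strict=False`` (default) malformed records are skipped with a
    warning naming the record index; with ``strict=True`` they raise.
    """
    mols: list[Molecule] = []
    for i, item in iter_sdf(path):
        if isinstance(item, Exception):
            if strict:
                raise item
            log.warning("skipping SDF record %d: %s", i, item)
        else:
            mols.append(item)
    return mols


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules back to SDF (V2000). Pass-through writer for fixtures."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rd = Chem.Mol(m.to_rdkit())
            rd.SetProp("_Name", m.name)
            writer.write(rd)
    finally:
        writer.close()


def embed_3d(mol: Molecule, seed: int = 2025, optimize: bool = True) -> Molecule:
    """Attach a 3D conformer (ETKDG + optional MMFF94 relaxation).

    Convenience for inputs drawn without coordinates whose perception needs
    the geometry-dependent specials (ring-angle bins, intramolecular
    H bridges). The resulting geometry is a force-field estimate, not the
    crystal or gas-phase structure.
    """
    rd = Chem.AddHs(Chem.Mol(mol.to_rdkit()))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise ValueError(f"3D embedding failed for {mol.name!r}")
    if optimize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            AllChem.MMFFOptimizeMolecule(rd)
    rd = Chem.RemoveHs(rd)
    return Molecule.from_rdkit(rd, name=mol.name)
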