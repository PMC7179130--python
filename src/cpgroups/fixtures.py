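"""Regression fixtures and synthetic training data.

Two things live here:

* the in-package fixture set — curated structures for the validation
  compounds (alkanols, alkanes/cycloalkanes, zwitterionic amino acids and
  ionic liquids) together with their printed group-additivity predictions
  and experimental Cp values. Records whose perception depends on 3D-only
  special groups (ring-angle bins, intramolecular H bridges) or on the
  unresolved polyol-correction multiplicity carry a non-empty ``flags``
  field and are excluded from strict regression comparisons.
* a deterministic synthetic-data generator for the fitting machinery:
  random sparse group-count vectors with full column rank whose targets are
  an exact additivity sum plus Gaussian noise. It emulates the structure of
  a real training set (integer counts, shared groups across molecules) but
  not its chemistry: collinearity between chemically correlated groups and
  heteroscedastic experimental error are absent.
"""
from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem_model import Molecule, read_smiles
from .group_perception import GroupCountVector
from .predictor import load_table

FIXTURE_SOURCES = ("T4", "T5", "T6", "T8", "T9", "T10")


@dataclass(frozen=True)
class FixtureRecord:
    name: str
    smiles: str
    phase: str                 # liquid | solid
    cp_printed_ga: float       # printed group-additivity prediction, J/mol/K
    cp_exp: float              # experimental value, J/mol/K
    source_table: str          # T4, T5, T6, T8, T9, T10
    flags: str = ""            # "", "polyol", "geometry"

    @property
    def strict(self) -> bool:
        """Eligible for strict regression (no 3D-only or unresolved specials)."""
        return not self.flags

    def molecule(self) -> Molecule:
        return read_smiles(self.smiles, name=self.name)


def build_fixture_set(sources: Optional[Sequence[str]] = None) -> list[FixtureRecord]:
    """Load the bundled fixture records (optionally filtered by source table)."""
    text = resources.files("cpgroups").joinpath("data/fixtures.tsv").read_text("utf-8")
    lines = text.splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        d = dict(zip(header, line.split("\t")))
        rec = FixtureRecord(
            name=d["name"],
            smiles=d["smiles"],
            phase=d["phase"],
            cp_printed_ga=float(d["cp_ga"]),
            cp_exp=float(d["cp_exp"]),
            source_table=d["source"],
            flags=d.get("flags", ""),
        )
        if sources is None or rec.source_table in sources:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# synthetic training data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Specification for a synthetic additivity training set.

    Defaults mirror the structure of the real regression problem at a
    desk-tractable size: 30 groups, 500 molecules, and a noise sigma of
    8 J/mol/K — the order of the residual standard deviation of the
    liquid-phase fit.
    """

    group_keys: list[str] = field(default_factory=list)
    true_contributions: list[float] = field(default_factory=list)
    n_molecules: int = 500
    noise_sigma: float = 8.0
    seed: int = 0
    min_groups_per_molecule: int = 2
    max_groups_per_molecule: int = 6
    max_count: int = 4

    def __post_init__(self):
        if not self.group_keys:
            keys, vals = _default_groups(30)
            self.group_keys = keys
            self.true_contributions = vals
        if len(self.group_keys) != len(self.true_contributions):
            raise ValueError("group_keys and true_contributions differ in length")
        if self.n_molecules < len(self.group_keys):
            raise ValueError("need at least as many molecules as groups")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _default_groups(n: int) -> tuple[list[str], list[float]]:
    """First n valid liquid-table groups and their contributions."""
    table = load_table("liquid")
    rows = sorted(
        (r for r in table.rows.values() if r.valid and not r.is_special),
        key=lambda r: -r.molecules,
    )[:n]
    return [r.key for r in rows], [r.contribution for r in rows]


def generate_synthetic_training(
    spec: SyntheticSpec, max_retries: int = 100
) -> list[tuple[GroupCountVector, float]]:
    """Draw a full-column-rank synthetic training set.

    Each molecule gets a random subset of groups with small positive
    counts; the target is the exact additivity sum plus N(0, sigma) noise.
    Deterministic under ``spec.seed``. Raises if no full-rank draw is found
    (pathological specs only).
    """
    rng = np.random.default_rng(spec.seed)
    n_groups = len(spec.group_keys)
    true = np.asarray(spec.true_contributions, dtype=float)
    for _ in range(max_retries):
        counts = np.zeros((spec.n_molecules, n_groups), dtype=int)
        for i in range(spec.n_molecules):
            k = rng.integers(spec.min_groups_per_molecule,
                             spec.max_groups_per_molecule + 1)
            cols = rng.choice(n_groups, size=min(k, n_groups), replace=False)
            counts[i, cols] = rng.integers(1, spec.max_count + 1, size=len(cols))
        support = (counts > 0).sum(axis=0)
        if np.any(support < 3):
            continue
        if np.linalg.matrix_rank(counts) < n_groups:
            continue
        noise = rng.normal(0.0, spec.noise_sigma, spec.n_molecules)
        targets = counts @ true + noise
        out = []
        for i in range(spec.n_molecules):
            gcv = GroupCountVector()
            for j in range(n_groups):
                if counts[i, j]:
                    gcv.atom_group_counts[spec.group_keys[j]] = int(counts[i, j])
            out.append((gcv, float(targets[i])))
        return out
    raise ValueError("could not draw a full-column-rank design (rank deficiency)")
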