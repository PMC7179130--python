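"""Group-additivity evaluation of Cp(298.15 K) against a contribution table.

The model is a plain additivity sum

    Cp = sum_i a_i A_i + sum_j b_j B_j          [J/mol/K]

where A_i counts the i-th atom group, B_j the j-th special group, and the
a_i/b_j are the phase-specific contributions shipped with the package
(liquid: 211 rows, solid: 197 rows, both including their special-group
rows). A contribution is *valid* for prediction when it was supported by at
least three independent molecules in the underlying regression; by default
the predictor refuses to use invalid rows (they are retained in the tables
for future refitting).

Disconnected records (ion pairs) are evaluated as one sum over the pooled
groups of all components; monatomic halide counter-ions have no backbone
atom and contribute zero.
"""
from __future__ import annotations

import importlib.resources as resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .chem_model import Molecule
from .group_perception import (
    ANGLE60, ANGLE90, ANGLE102, COHN, ENDOCYCLIC, HH_ACCEPTOR,
    GroupCountVector, PerceptionConfig, SPECIAL_KEYS, perceive,
)

log = logging.getLogger(__name__)

PHASES = ("liquid", "solid")
MIN_MOLECULES_VALID = 3

# table text -> canonical special key
_SPECIAL_ATOM_TYPES = {
    "(COH)n": COHN,
    "H": HH_ACCEPTOR,
    "Endocyclic bonds": ENDOCYCLIC,
    "Angle60": ANGLE60,
    "Angle90": ANGLE90,
    "Angle102": ANGLE102,
}


class TableError(ValueError):
    """Malformed contribution table."""


@dataclass(frozen=True)
class ContributionRow:
    entry: int
    key: str                 # "atom type|neighbours" or canonical special key
    contribution: float      # J/mol/K
    occurrences: int
    molecules: int
    is_special: bool

    @property
    def valid(self) -> bool:
        return self.molecules >= MIN_MOLECULES_VALID


@dataclass
class ContributionTable:
    phase: str
    rows: dict[str, ContributionRow]
    source: str = ""

    @property
    def keys(self) -> set[str]:
        return set(self.rows)

    @property
    def n_valid(self) -> int:
        return sum(1 for r in self.rows.values() if r.valid)

    def __contains__(self, key: str) -> bool:
        return key in self.rows


@dataclass
class Prediction:
    """Result of one Eq.-style additivity evaluation, with full audit trail."""

    name: str
    cp: Optional[float]                       # J/mol/K at 298.15 K; None if not computable
    breakdown: list[tuple[str, int, float, float]] = field(default_factory=list)
    missing_groups: list[str] = field(default_factory=list)
    used_invalid_groups: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    counts: Optional[GroupCountVector] = None

    @property
    def computable(self) -> bool:
        return self.cp is not None


def load_table(path_or_phase: Union[str, Path], phase: Optional[str] = None) -> ContributionTable:
    """Load a contribution table from TSV.

    ``load_table("liquid")`` / ``load_table("solid")`` load the bundled
    tables; otherwise the argument is a path to a TSV with columns
    (entry, atom_type, neighbours, contribution, occurrences, molecules).
    """
    if str(path_or_phase) in PHASES:
        phase = str(path_or_phase)
        ref = resources.files("cpgroups").joinpath(
            f"data/cp_{'liquid' if phase == 'liquid' else 'solid'}.tsv"
        )
        text = ref.read_text(encoding="utf-8")
        source = f"bundled:{phase}"
    else:
        if phase not in PHASES:
            raise TableError(f"phase must be one of {PHASES}, got {phase!r}")
        text = Path(path_or_phase).read_text(encoding="utf-8")
        source = str(path_or_phase)
    rows: dict[str, ContributionRow] = {}
    lines = text.splitlines()
    header = lines[0].split("\t")
    idx = {c: k for k, c in enumerate(header)}
    for col in ("entry", "atom_type", "neighbours", "contribution", "occurrences", "molecules"):
        if col not in idx:
            raise TableError(f"{source}: missing column {col!r}")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        atom_type = parts[idx["atom_type"]].strip()
        neighbours = parts[idx["neighbours"]].strip()
        special = _SPECIAL_ATOM_TYPES.get(atom_type)
        is_special = special is not None and (
            atom_type != "H" or neighbours == "H Acceptor"
        )
        key = special if is_special else f"{atom_type}|{neighbours}"
        try:
            contribution = float(parts[idx["contribution"]])
            occurrences = int(parts[idx["occurrences"]] or 0)
            molecules = int(parts[idx["molecules"]] or 0)
            entry = int(parts[idx["entry"]])
        except ValueError as exc:
            raise TableError(f"{source}:{ln}: non-numeric field ({exc})") from None
        if key in rows:
            raise TableError(f"{source}:{ln}: duplicate group key {key!r}")
        rows[key] = ContributionRow(entry, key, contribution, occurrences, molecules, is_special)
    return ContributionTable(phase=phase, rows=rows, source=source)


@dataclass
class PredictorConfig:
    """Policy knobs for the additivity evaluation."""

    allow_invalid_groups: bool = False
    perception: PerceptionConfig = field(default_factory=PerceptionConfig)


def predict_from_counts(
    counts: GroupCountVector,
    table: ContributionTable,
    name: str = "",
    config: Optional[PredictorConfig] = None,
) -> Prediction:
    """Evaluate the additivity sum for an already-perceived count vector."""
    config = config or PredictorConfig()
    pred = Prediction(name=name, cp=None, counts=counts)
    total = 0.0
    ok = True
    for key, count in sorted(counts.atom_group_counts.items()):
        row = table.rows.get(key)
        if row is None:
            pred.missing_groups.append(key)
            ok = False
            continue
        if not row.valid:
            pred.used_invalid_groups.append(key)
            if not config.allow_invalid_groups:
                ok = False
                continue
        pred.breakdown.append((key, count, row.contribution, count * row.contribution))
        total += count * row.contribution
    for key in SPECIAL_KEYS:
        count = counts.special_counts.get(key, 0)
        if not count:
            continue
        row = table.rows.get(key)
        if row is None:
            pred.warnings.append(
                f"special group {key!r} (count {count}) has no row in the "
                f"{table.phase} table and is ignored"
            )
            continue
        if not row.valid:
            pred.used_invalid_groups.append(key)
            if not config.allow_invalid_groups:
                ok = False
                continue
        pred.breakdown.append((key, count, row.contribution, count * row.contribution))
        total += count * row.contribution
    if ok:
        pred.cp = total
    return pred


def predict_cp(
    mol: Molecule,
    table: ContributionTable,
    config: Optional[PredictorConfig] = None,
) -> Prediction:
    """Perceive a molecule and evaluate its Cp against ``table``.

    A group absent from the table makes the result not-computable (``cp`` is
    None and ``missing_groups`` names the offenders) rather than raising:
    limited applicability is an expected outcome of a group-contribution
    scheme. Charged monatomic components (halide counter-ions) contribute
    nothing and are flagged with a warning.
    """
    config = config or PredictorConfig()
    counts = perceive(mol, config.perception, table_keys=table.keys)
    pred = predict_from_counts(counts, table, name=mol.name, config=config)
    for a in mol.atoms:
        if a.formal_charge != 0 and not mol.neighbors(a.index):
            pred.warnings.append(
                f"monatomic ion {a.element}{'+' if a.formal_charge > 0 else '-'} "
                f"(atom {a.index}) carries no group and contributes 0"
            )
    if not mol.has_coords and any(
        counts.special_counts.get(k, 0) for k in (ANGLE102,)
    ):
        pred.warnings.append("Angle102 counted without coordinates")
    return pred
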