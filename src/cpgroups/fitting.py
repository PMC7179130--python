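"""Re-derivation of group contributions from a training set.

The pipeline mirrors the one that produced the shipped tables: the group
occurrences of M compounds form an M x N occurrence matrix G with the
experimental Cp values as targets y; the matrix is normalised to the
normal equations (G'G) x = G'y and balanced by Gauss-Seidel iteration;
a 10-fold cross-validation rates the fit (q2, cross-validated deviations);
group contributions supported by fewer than three distinct molecules are
marked invalid; compounds deviating by more than three cross-validated
standard deviations are removed as outliers and the fit repeats until no
removals remain.

Statistics semantics: r2/q2 are squared Pearson correlations between
predicted and experimental values (an R2 = 1 - SSE/SST variant is emitted
alongside), avg_dev is the mean absolute deviation, std_dev the
root-mean-square deviation with n-1 in the denominator, and MAPD the mean
absolute percentage deviation 100/n * sum(|calc - exp| / exp).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_model import Molecule
from .group_perception import GroupCountVector, PerceptionConfig, perceive
from .predictor import MIN_MOLECULES_VALID

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 200_000
OUTLIER_SD_MULTIPLE = 3.0
# absolute floor on the outlier limit: an (essentially) exact fit has an SD on
# the order of the solver tolerance, and 3x that must not flag numerical noise
OUTLIER_LIMIT_FLOOR = 1e-6


class FittingError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Occurrence matrix: rows = compounds, columns = group keys."""

    counts: pd.DataFrame          # M x N non-negative integer counts
    target: np.ndarray            # M experimental Cp values, J/mol/K
    names: list[str]

    @property
    def group_keys(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_compounds(self) -> int:
        return len(self.counts)

    def molecule_support(self) -> pd.Series:
        """Distinct-molecule support per group (rows with a nonzero count)."""
        return (self.counts > 0).sum(axis=0)

    def subset(self, row_mask: np.ndarray) -> "DesignMatrix":
        sub = self.counts.loc[row_mask]
        keep = sub.columns[(sub > 0).any(axis=0)]
        return DesignMatrix(
            counts=sub[keep].reset_index(drop=True),
            target=self.target[row_mask],
            names=[n for n, m in zip(self.names, row_mask) if m],
        )


@dataclass
class FitStatistics:
    r2: float                    # squared Pearson correlation, training fit
    r2_sse: float                # 1 - SSE/SST variant
    avg_dev: float               # J/mol/K
    std_dev: float               # J/mol/K
    mapd: float                  # percent
    n_fit: int
    q2: Optional[float] = None   # pooled cross-validation
    avg_dev_cv: Optional[float] = None
    std_dev_cv: Optional[float] = None
    n_cv: Optional[int] = None


@dataclass
class FitResult:
    contributions: pd.Series          # J/mol/K per group key
    support: pd.Series                # distinct-molecule support per group
    valid: pd.Series                  # support >= 3
    stats: FitStatistics
    outliers: list[tuple[str, float]] = field(default_factory=list)
    seed: Optional[int] = None
    n_iterations: int = 1

    def to_table_frame(self, phase: str) -> pd.DataFrame:
        """Rows compatible with predictor.load_table (TSV round-trip)."""
        from .group_perception import SPECIAL_KEYS
        rows = []
        for entry, key in enumerate(self.contributions.index, start=1):
            if key in SPECIAL_KEYS:
                atom_type, neighbours = key, ""
            else:
                atom_type, neighbours = key.split("|", 1)
            rows.append({
                "entry": entry,
                "atom_type": atom_type,
                "neighbours": neighbours,
                "contribution": round(float(self.contributions[key]), 4),
                "occurrences": 0,
                "molecules": int(self.support[key]),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def assemble(
    compounds: Sequence[tuple[Molecule, float]],
    config: Optional[PerceptionConfig] = None,
) -> DesignMatrix:
    """Build the occurrence matrix for (molecule, experimental Cp) pairs.

    Compounds whose perception fails are skipped with a log entry; an empty
    usable set raises.
    """
    rows: list[dict[str, int]] = []
    targets: list[float] = []
    names: list[str] = []
    for mol, cp in compounds:
        try:
            gcv = perceive(mol, config)
        except Exception as exc:  # noqa: BLE001 - perception errors are data errors
            log.warning("skipping %s: perception failed (%s)", mol.name, exc)
            continue
        rows.append(gcv.all_counts())
        targets.append(float(cp))
        names.append(mol.name)
    if not rows:
        raise FittingError("no usable compounds")
    counts = pd.DataFrame(rows).fillna(0).astype(int)
    counts = counts[sorted(counts.columns)]
    return DesignMatrix(counts=counts, target=np.asarray(targets, dtype=float), names=names)


def from_count_vectors(
    items: Sequence[tuple[GroupCountVector, float]],
    names: Optional[Sequence[str]] = None,
) -> DesignMatrix:
    """Design matrix directly from pre-perceived count vectors."""
    if not items:
        raise FittingError("no usable compounds")
    rows = [gcv.all_counts() for gcv, _ in items]
    counts = pd.DataFrame(rows).fillna(0).astype(int)
    counts = counts[sorted(counts.columns)]
    return DesignMatrix(
        counts=counts,
        target=np.asarray([cp for _, cp in items], dtype=float),
        names=list(names) if names else [f"synthetic{i}" for i in range(len(items))],
    )


# ---------------------------------------------------------------------------
# Gauss-Seidel solver on the normal equations
# ---------------------------------------------------------------------------

def solve_gauss_seidel(
    dm: DesignMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> pd.Series:
    """Least-squares contributions via Gauss-Seidel on (G'G) x = G'y.

    The normal-equations matrix of a full-column-rank occurrence matrix is
    symmetric positive definite, for which the sweep converges to the
    least-squares solution. Iteration stops when the largest coordinate
    change falls below ``tol``.
    """
    G = dm.counts.to_numpy(dtype=float)
    y = dm.target
    A = G.T @ G
    b = G.T @ y
    d = np.diag(A)
    if np.any(d == 0):
        bad = dm.group_keys[int(np.argmin(d != 0))]
        raise FittingError(f"degenerate column (zero diagonal) for group {bad!r}")
    x = b / d  # warm start: per-group mean scale
    L = np.tril(A)
    U = np.triu(A, k=1)
    prev_delta = None
    for _ in range(max_iter):
        # one Gauss-Seidel sweep in matrix form: L x_new = b - U x_old
        # (identical to the coordinate-wise update, forward substitution)
        x_new = np.linalg.solve(L, b - U @ x)
        delta = float(np.max(np.abs(x_new - x)))
        x = x_new
        if delta == 0.0:
            break
        # linear convergence: error ~ delta * q/(1-q); the raw step size
        # understates the error badly when the contraction factor q -> 1
        # (nearly collinear columns), so stop on the geometric estimate
        if prev_delta is not None and prev_delta > 0.0:
            q = delta / prev_delta
            if q < 1.0 and delta * q / (1.0 - q) < tol:
                break
        # stagnation at machine precision
        if delta < 1e-14 * max(1.0, float(np.max(np.abs(x)))):
            break
        prev_delta = delta
    else:
        resid = float(np.linalg.norm(A @ x - b))
        raise FittingError(
            f"Gauss-Seidel did not converge in {max_iter} sweeps "
            f"(last residual norm {resid:.3e})"
        )
    return pd.Series(x, index=dm.group_keys)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def compute_statistics(pred: np.ndarray, exp: np.ndarray) -> dict[str, float]:
    """r2 (Pearson squared), R2 (1-SSE/SST), avg/std deviation, MAPD."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if len(pred) != len(exp) or len(pred) < 2:
        raise FittingError("need paired vectors of length >= 2")
    if np.any(exp == 0):
        raise FittingError("zero experimental value (MAPD undefined)")
    delta = pred - exp
    sd_p, sd_e = np.std(pred), np.std(exp)
    if sd_p == 0 or sd_e == 0:
        r2 = 1.0 if np.allclose(pred - pred.mean(), exp - exp.mean()) else 0.0
    else:
        r2 = float(np.corrcoef(pred, exp)[0, 1] ** 2)
    sst = float(np.sum((exp - exp.mean()) ** 2))
    r2_sse = 1.0 - float(np.sum(delta**2)) / sst if sst > 0 else float("nan")
    return {
        "r2": r2,
        "r2_sse": r2_sse,
        "avg_dev": float(np.mean(np.abs(delta))),
        "std_dev": float(np.sqrt(np.sum(delta**2) / (len(delta) - 1))),
        "mapd": float(100.0 * np.mean(np.abs(delta) / np.abs(exp))),
        "n": len(delta),
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidation:
    predictions: np.ndarray       # pooled held-out predictions (NaN = excluded)
    excluded: list[int]           # row indices excluded (under-supported groups)
    folds: list[np.ndarray]

    @property
    def included_mask(self) -> np.ndarray:
        return ~np.isnan(self.predictions)


def cross_validate(
    dm: DesignMatrix,
    k: int = 10,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    min_support: int = MIN_MOLECULES_VALID,
) -> CrossValidation:
    """K-fold cross-validation with pooled held-out predictions.

    Compounds are shuffled (seeded) into k near-equal folds; each compound
    is predicted exactly once from a model fitted without its fold.
    Held-out compounds that require a group with zero training support
    cannot be predicted, and ones whose groups fall below ``min_support``
    distinct training molecules are excluded from the CV statistics as
    well - this reproduces the pattern that the cross-validated compound
    count is smaller than the fitted one.
    """
    if k < 2:
        raise FittingError("k must be >= 2")
    m = dm.n_compounds
    if k > m:
        raise FittingError(f"k={k} exceeds the number of compounds ({m})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = [order[i::k] for i in range(k)]
    pooled = np.full(m, np.nan)
    excluded: list[int] = []
    for fold in folds:
        test_mask = np.zeros(m, dtype=bool)
        test_mask[fold] = True
        train = dm.subset(~test_mask)
        contribs = solve_gauss_seidel(train, tol=tol, max_iter=max_iter)
        support = train.molecule_support()
        usable = {g for g in train.group_keys if support[g] >= min_support}
        for i in fold:
            row = dm.counts.iloc[i]
            needed = set(row.index[row > 0])
            if not needed <= usable:
                excluded.append(int(i))
                continue
            pooled[i] = float(sum(row[g] * contribs[g] for g in needed))
    return CrossValidation(predictions=pooled, excluded=sorted(excluded), folds=folds)


# ---------------------------------------------------------------------------
# full fit with outlier elimination
# ---------------------------------------------------------------------------

def fit_design_matrix(
    dm: DesignMatrix,
    k: int = 10,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    outlier_multiple: float = OUTLIER_SD_MULTIPLE,
    max_outlier_rounds: int = 20,
) -> FitResult:
    """Fit, cross-validate, and iterate 3xSD outlier removal to convergence.

    Per round: solve the full normal equations, cross-validate, and remove
    every compound whose training residual exceeds ``outlier_multiple``
    times the cross-validated standard deviation (batch removal). Validity
    flags are set from distinct-molecule support; the headline statistics
    are computed only over compounds all of whose groups are valid.
    """
    if dm.n_compounds < 2:
        raise FittingError("need at least two compounds")
    work = dm
    removed: list[tuple[str, float]] = []
    for round_no in range(1, max_outlier_rounds + 1):
        contribs = solve_gauss_seidel(work, tol=tol, max_iter=max_iter)
        fitted = work.counts.to_numpy(dtype=float) @ contribs.to_numpy()
        cv = cross_validate(work, k=min(k, work.n_compounds), seed=seed,
                            tol=tol, max_iter=max_iter)
        mask_cv = cv.included_mask
        if mask_cv.sum() >= 2:
            cv_stats = compute_statistics(cv.predictions[mask_cv], work.target[mask_cv])
            limit = outlier_multiple * cv_stats["std_dev"]
        else:
            cv_stats = None
            limit = outlier_multiple * compute_statistics(fitted, work.target)["std_dev"]
        limit = max(limit, OUTLIER_LIMIT_FLOOR)
        resid = fitted - work.target
        violators = np.abs(resid) > limit
        if not violators.any():
            break
        for i in np.nonzero(violators)[0]:
            removed.append((work.names[i], float(resid[i])))
        log.info("outlier round %d: removed %d compounds (limit %.3f)",
                 round_no, int(violators.sum()), limit)
        work = work.subset(~violators)
        if work.n_compounds < 2:
            raise FittingError("outlier loop removed nearly all compounds")
    else:
        raise FittingError(
            f"outlier elimination did not terminate in {max_outlier_rounds} rounds"
        )

    support = work.molecule_support()
    valid = support >= MIN_MOLECULES_VALID
    all_valid_rows = np.asarray(
        [(work.counts.iloc[i][work.counts.iloc[i] > 0].index.map(valid).all())
         for i in range(work.n_compounds)]
    )
    stat_mask = all_valid_rows
    if stat_mask.sum() >= 2:
        train_stats = compute_statistics(fitted[stat_mask], work.target[stat_mask])
    else:
        train_stats = compute_statistics(fitted, work.target)
    cv_pool = cv.included_mask & stat_mask
    stats = FitStatistics(
        r2=train_stats["r2"],
        r2_sse=train_stats["r2_sse"],
        avg_dev=train_stats["avg_dev"],
        std_dev=train_stats["std_dev"],
        mapd=train_stats["mapd"],
        n_fit=int(stat_mask.sum()),
    )
    if cv_pool.sum() >= 2:
        cvs = compute_statistics(cv.predictions[cv_pool], work.target[cv_pool])
        stats.q2 = cvs["r2"]
        stats.avg_dev_cv = cvs["avg_dev"]
        stats.std_dev_cv = cvs["std_dev"]
        stats.n_cv = int(cv_pool.sum())
    return FitResult(
        contributions=contribs,
        support=support,
        valid=valid,
        stats=stats,
        outliers=removed,
        seed=seed,
        n_iterations=round_no,
    )


def fit_with_outlier_loop(
    compounds: Sequence[tuple[Molecule, float]],
    k: int = 10,
    seed: int = 0,
    config: Optional[PerceptionConfig] = None,
    **kwargs,
) -> FitResult:
    """Convenience: assemble from molecules then run the full fitting loop."""
    return fit_design_matrix(assemble(compounds, config), k=k, seed=seed, **kwargs)
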