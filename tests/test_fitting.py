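"""Occurrence-matrix fitting: Gauss-Seidel, cross-validation, outlier loop."""
import numpy as np
import pandas as pd
import pytest

from cpgroups.chem_model import read_smiles
from cpgroups.fitting import (
    DesignMatrix,
    FittingError,
    assemble,
    compute_statistics,
    cross_validate,
    fit_design_matrix,
    from_count_vectors,
    solve_gauss_seidel,
)
from cpgroups.fixtures import SyntheticSpec, generate_synthetic_training


def make_dm(G, y, keys=None):
    keys = keys or [f"g{i}" for i in range(G.shape[1])]
    return DesignMatrix(pd.DataFrame(G, columns=keys), np.asarray(y, float),
                        [f"c{i}" for i in range(len(y))])


# -- assembly ---------------------------------------------------------------

def test_assemble_ethane_single_cell():
    dm = assemble([(read_smiles("CC", "ethane"), 52.5)])
    assert dm.counts.shape == (1, 1)
    assert dm.counts.iloc[0]["C sp3|H3C"] == 2


def test_assemble_hexane_cyclohexane_columns():
    dm = assemble([
        (read_smiles("CCCCCC", "hexane"), 197.66),
        (read_smiles("C1CCCCC1", "cyclohexane"), 158.10),
    ])
    assert set(dm.group_keys) == {"C sp3|H3C", "C sp3|H2C2", "Endocyclic bonds"}
    hexane = dm.counts.iloc[0]
    cyclohexane = dm.counts.iloc[1]
    assert (hexane["C sp3|H3C"], hexane["C sp3|H2C2"], hexane["Endocyclic bonds"]) == (2, 4, 0)
    assert (cyclohexane["C sp3|H3C"], cyclohexane["C sp3|H2C2"],
            cyclohexane["Endocyclic bonds"]) == (0, 6, 6)


def test_assemble_empty_input_errors():
    with pytest.raises(FittingError, match="no usable compounds"):
        assemble([])


# -- Gauss-Seidel solver ----------------------------------------------------

def test_identity_design_returns_targets():
    y = np.array([10.0, 20.0, 30.0])
    x = solve_gauss_seidel(make_dm(np.eye(3, dtype=int), y))
    np.testing.assert_allclose(x.values, y, atol=1e-8)


def test_two_compound_closed_form():
    dm = make_dm(np.array([[2, 0], [2, 4]]), [74.06, 194.30])
    x = solve_gauss_seidel(dm)
    np.testing.assert_allclose(x.values, [37.03, 30.06], atol=1e-8)


@pytest.mark.parametrize("n_groups", [5, 12, 25, 50])
def test_gauss_seidel_matches_least_squares_oracle(n_groups):
    rng = np.random.default_rng(n_groups)
    G = rng.poisson(1.0, size=(4 * n_groups, n_groups)) + (
        rng.random((4 * n_groups, n_groups)) < 0.3
    )
    while np.linalg.matrix_rank(G) < n_groups:
        G = rng.poisson(1.0, size=(4 * n_groups, n_groups))
    y = rng.normal(250.0, 60.0, 4 * n_groups)
    x = solve_gauss_seidel(make_dm(G, y))
    ref, *_ = np.linalg.lstsq(G.astype(float), y, rcond=None)
    assert np.max(np.abs(x.values - ref)) < 1e-6


def test_degenerate_column_raises():
    G = np.array([[1, 0], [2, 0]])
    with pytest.raises(FittingError, match="degenerate column"):
        solve_gauss_seidel(make_dm(G, [1.0, 2.0]))


# -- statistics -------------------------------------------------------------

def test_statistics_perfect_fit():
    s = compute_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert s["r2"] == pytest.approx(1.0)
    assert s["mapd"] == 0.0 and s["std_dev"] == 0.0


def test_statistics_constant_shift():
    exp = np.array([100.0, 150.0, 210.0, 300.0])
    s = compute_statistics(exp + 5.0, exp)
    assert s["r2"] == pytest.approx(1.0)
    assert s["avg_dev"] == pytest.approx(5.0)
    # rms with n-1: sqrt(4*25/3)
    assert s["std_dev"] == pytest.approx(np.sqrt(100.0 / 3.0))


def test_statistics_two_point_mapd_hand_value():
    s = compute_statistics([110.0, 190.0], [100.0, 200.0])
    assert s["mapd"] == pytest.approx(7.5)


def test_statistics_errors():
    with pytest.raises(FittingError):
        compute_statistics([1.0], [1.0])
    with pytest.raises(FittingError):
        compute_statistics([1.0, 2.0], [0.0, 2.0])


# -- cross-validation -------------------------------------------------------

def test_cv_perfect_linear_data_gives_q2_one():
    data = generate_synthetic_training(SyntheticSpec(n_molecules=120, noise_sigma=0.0, seed=3))
    dm = from_count_vectors(data)
    cv = cross_validate(dm, k=10, seed=0)
    m = cv.included_mask
    s = compute_statistics(cv.predictions[m], dm.target[m])
    assert s["r2"] == pytest.approx(1.0, abs=1e-9)
    assert s["std_dev"] == pytest.approx(0.0, abs=1e-6)


def test_cv_excludes_compound_with_unique_group():
    rng = np.random.default_rng(0)
    G = rng.integers(1, 3, size=(30, 3))
    G = np.hstack([G, np.zeros((30, 1), dtype=int)])
    G[7, 3] = 2  # group g3 exists only in compound 7
    y = G @ np.array([30.0, 40.0, 50.0, 60.0])
    cv = cross_validate(make_dm(G, y), k=5, seed=1)
    assert 7 in cv.excluded
    assert np.isnan(cv.predictions[7])


def test_cv_fold_partition_is_exact():
    data = generate_synthetic_training(SyntheticSpec(n_molecules=57, noise_sigma=1.0, seed=5))
    dm = from_count_vectors(data)
    cv = cross_validate(dm, k=10, seed=2)
    all_idx = np.concatenate(cv.folds)
    assert sorted(all_idx) == list(range(57))  # each compound held out exactly once


def test_cv_parameter_validation():
    data = generate_synthetic_training(SyntheticSpec(n_molecules=40, seed=1))
    dm = from_count_vectors(data)
    with pytest.raises(FittingError):
        cross_validate(dm, k=1)
    with pytest.raises(FittingError):
        cross_validate(dm, k=41)


# -- full fit with outlier loop --------------------------------------------

def test_clean_synthetic_set_recovers_contributions_without_outliers():
    spec = SyntheticSpec(n_molecules=150, noise_sigma=0.0, seed=11)
    data = generate_synthetic_training(spec)
    result = fit_design_matrix(from_count_vectors(data), k=10, seed=0)
    assert result.outliers == []
    recovered = result.contributions[spec.group_keys].to_numpy()
    assert np.max(np.abs(recovered - np.asarray(spec.true_contributions))) < 1e-6


def test_implanted_gross_error_is_the_only_outlier():
    spec = SyntheticSpec(n_molecules=300, noise_sigma=8.0, seed=21)
    data = generate_synthetic_training(spec)
    gcv, cp = data[50]
    data[50] = (gcv, cp + 10 * spec.noise_sigma)
    dm = from_count_vectors(data)
    result = fit_design_matrix(dm, k=10, seed=0)
    assert [name for name, _ in result.outliers] == [dm.names[50]]


def test_removing_outlier_decreases_std_dev():
    spec = SyntheticSpec(n_molecules=200, noise_sigma=8.0, seed=31)
    data = generate_synthetic_training(spec)
    gcv, cp = data[10]
    data[10] = (gcv, cp + 10 * spec.noise_sigma)
    dm = from_count_vectors(data)
    contribs = solve_gauss_seidel(dm)
    fitted = dm.counts.to_numpy(float) @ contribs.to_numpy()
    sd_with = compute_statistics(fitted, dm.target)["std_dev"]
    result = fit_design_matrix(dm, k=10, seed=0)
    assert result.stats.std_dev < sd_with


def test_validity_flags_follow_molecule_support():
    rng = np.random.default_rng(2)
    G = rng.integers(1, 3, size=(40, 4))
    G = np.hstack([G, np.zeros((40, 2), dtype=int)])
    G[0, 4] = G[1, 4] = 1          # group g4: 2 molecules -> invalid
    G[0, 5] = G[1, 5] = G[2, 5] = 1  # group g5: 3 molecules -> valid
    y = G @ rng.normal(40, 10, 6)
    result = fit_design_matrix(make_dm(G, y), k=5, seed=0)
    assert not result.valid["g4"]
    assert result.valid["g5"]
    assert result.stats.n_fit < 40  # compounds touching g4 drop from the stats


def test_noise_recovery_is_unbiased_over_replicates():
    spec0 = SyntheticSpec(n_molecules=150, noise_sigma=8.0, seed=0)
    true = np.asarray(spec0.true_contributions)
    errors = np.zeros_like(true)
    n_rep = 50
    for seed in range(n_rep):
        spec = SyntheticSpec(n_molecules=150, noise_sigma=8.0, seed=seed)
        data = generate_synthetic_training(spec)
        dm = from_count_vectors(data)
        x = solve_gauss_seidel(dm)
        errors += x[spec.group_keys].to_numpy() - true
    bias = errors / n_rep
    # mean bias per group shrinks as 1/sqrt(n_rep); allow 4 standard errors
    assert np.max(np.abs(bias)) < 2.0
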