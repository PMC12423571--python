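import numpy as np
import pandas as pd
import pytest

from seedpath.assemblage import build_grid
from seedpath.model import parse_model
from seedpath.sem import SemData
from seedpath.spatial import (
    NullDistribution,
    build_weights,
    fit_sar_error,
    morans_i,
    permutation_null,
)
from seedpath.synthetic import simulate_sem_table, theta_from_maps


def lattice_table(n_rows: int, n_cols: int) -> tuple[pd.DataFrame, object]:
    size = 10_000.0
    grid = build_grid((0, 0, n_cols * size, n_rows * size), size)
    cents = grid.centroids()
    table = pd.DataFrame(
        {"cell_id": np.arange(grid.n_cells), "x": cents[:, 0], "y": cents[:, 1]}
    )
    return table, grid


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------
def test_rook_weights_on_2x2_lattice():
    table, grid = lattice_table(2, 2)
    w = build_weights(table, grid, scheme="rook", row_standardize=False)
    deg = np.asarray(w.w.sum(axis=1)).ravel()
    assert np.all(deg == 2)
    assert np.allclose(w.w.toarray(), w.w.toarray().T)
    assert np.all(w.w.diagonal() == 0)


def test_row_standardized_rows_sum_to_one():
    table, grid = lattice_table(4, 5)
    w = build_weights(table, grid, scheme="queen", row_standardize=True)
    assert np.allclose(np.asarray(w.w.sum(axis=1)).ravel(), 1.0)


def test_knn_full_connection():
    table, grid = lattice_table(2, 3)
    w = build_weights(table, grid, scheme="knn", row_standardize=False, k=5)
    dense = w.w.toarray()
    assert np.all(dense[~np.eye(6, dtype=bool)] == 1.0)


def test_isolated_cell_linked_to_nearest():
    table, grid = lattice_table(3, 3)
    island = table[table.cell_id.isin([0, 8])].reset_index(drop=True)
    with pytest.warns(UserWarning, match="isolated"):
        w = build_weights(island, grid, scheme="rook", row_standardize=False)
    assert np.asarray(w.w.sum(axis=1)).ravel().min() >= 1


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------
def test_checkerboard_moran_is_minus_one():
    table, grid = lattice_table(2, 2)
    w = build_weights(table, grid, scheme="rook", row_standardize=False)
    res = morans_i(np.array([1.0, -1.0, -1.0, 1.0]), w, n_perm=0)
    assert res["I"] == pytest.approx(-1.0)


def test_moran_expectation_formula():
    table, grid = lattice_table(19, 19)
    w = build_weights(table, grid, scheme="queen")
    res = morans_i(np.random.default_rng(0).normal(size=361), w, n_perm=0)
    assert res["expected"] == pytest.approx(-1.0 / 360.0)


def test_moran_constant_values_rejected():
    table, grid = lattice_table(2, 3)
    w = build_weights(table, grid, scheme="rook")
    with pytest.raises(ValueError, match="constant"):
        morans_i(np.ones(6), w)


def test_moran_null_behaviour_for_shuffled_values():
    table, grid = lattice_table(8, 8)
    w = build_weights(table, grid, scheme="queen")
    rng = np.random.default_rng(1)
    ps, Is = [], []
    for k in range(20):
        res = morans_i(rng.normal(size=64), w, n_perm=199, seed=k)
        ps.append(res["p"])
        Is.append(res["I"])
    assert abs(np.mean(Is) - (-1 / 63)) < 0.05
    assert min(ps) > 0  # add-one rule: p never zero
    assert np.mean(np.array(ps) < 0.05) <= 0.25


def test_moran_bounded_by_extreme_rayleigh_quotients():
    """|I| cannot exceed the extreme eigenvalue bound of the doubly
    centred weight structure; checked against a brute-force scan."""
    table, grid = lattice_table(4, 4)
    w = build_weights(table, grid, scheme="queen", row_standardize=False)
    n = 16
    W = w.w.toarray()
    M = np.eye(n) - np.ones((n, n)) / n
    A = M @ (W + W.T) / 2 @ M * (n / W.sum())
    evals = np.linalg.eigvalsh(A)
    rng = np.random.default_rng(2)
    worst = 0.0
    for _ in range(10_000):
        v = rng.normal(size=n)
        worst = max(worst, abs(morans_i(v, w, n_perm=0)["I"]))
    assert worst <= max(abs(evals[0]), abs(evals[-1])) + 1e-9


# ---------------------------------------------------------------------------
# SAR error model
# ---------------------------------------------------------------------------
def test_sar_reduces_to_ols_at_lambda_zero():
    table, grid = lattice_table(20, 20)
    w = build_weights(table, grid, scheme="queen", row_standardize=True)
    rng = np.random.default_rng(3)
    X = rng.normal(size=(400, 2))
    beta = np.array([1.0, 0.5, -0.8])
    y = beta[0] + X @ beta[1:] + rng.normal(0, 0.5, 400)
    ols = np.linalg.lstsq(np.column_stack([np.ones(400), X]), y, rcond=None)[0]
    # evaluated at lam = 0 the profiled solution is exactly least squares
    fixed = fit_sar_error(y, X, w, lam=0.0)
    assert np.allclose(fixed["beta"], ols, atol=1e-10)
    resid = y - np.column_stack([np.ones(400), X]) @ ols
    assert fixed["sigma2"] == pytest.approx(float(resid @ resid) / 400)
    # and the ML estimate of lambda on lambda-free data sits near zero
    free = fit_sar_error(y, X, w)
    assert abs(free["lambda"]) < 0.15
    assert np.allclose(free["beta"], ols, atol=5e-3)


def test_sar_loglik_profile_maximality():
    table, grid = lattice_table(12, 12)
    w = build_weights(table, grid, scheme="queen", row_standardize=True)
    rng = np.random.default_rng(4)
    n = 144
    X = rng.normal(size=(n, 1))
    Wd = w.w.toarray()
    u = np.linalg.solve(np.eye(n) - 0.6 * Wd, rng.normal(0, 0.4, n))
    y = 0.5 + 0.8 * X[:, 0] + u
    res = fit_sar_error(y, X, w)
    # log-likelihood at the estimate beats the OLS boundary lam = 0
    ev = np.linalg.eigvals(Wd).real
    A0 = np.eye(n)
    b0 = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
    rss0 = float(np.sum((y - np.column_stack([np.ones(n), X]) @ b0) ** 2))
    ll0 = -n / 2 * (np.log(2 * np.pi) + 1) - n / 2 * np.log(rss0 / n)
    assert res["loglik"] >= ll0 - 1e-8


def test_sar_rank_deficient_design_rejected():
    table, grid = lattice_table(3, 3)
    w = build_weights(table, grid, scheme="queen", row_standardize=True)
    X = np.ones((9, 2))
    with pytest.raises(ValueError, match="rank"):
        fit_sar_error(np.arange(9.0), X, w)


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------
def test_add_one_empirical_p_floor():
    null = np.full((1000, 1), 0.01)
    nd = NullDistribution(
        labels=["seed~x"], observed=np.array([0.9]), null=null,
        n_perm=1000, n_failed=0, seed=0,
    )
    assert nd.empirical_p[0] == pytest.approx(1.0 / 1001.0)


@pytest.fixture(scope="module")
def perm_setup():
    model = parse_model("seed ~ e\ne ~ h", variables=["seed", "e", "h"])
    theta = theta_from_maps(
        model, {("seed", "e"): 0.6, ("e", "h"): -0.5},
        {"seed": 0.5, "e": 0.75, "h": 1.0},
    )
    rng = np.random.default_rng(6)
    table = simulate_sem_table(model, theta, 300, seed=15)
    table = np.exp(table)  # strictly positive for the log transform
    return model, table


def test_permutation_preserves_value_multiset(perm_setup):
    model, table = perm_setup
    seen = []

    def capture(t):
        seen.append(sorted(t["seed"].to_numpy()))
        from seedpath.sem import preprocess_variables

        return preprocess_variables(t, variables=list(model.variables))

    permutation_null(table, model, n_perm=5, seed=1, preprocess=capture)
    reference = sorted(table["seed"].to_numpy())
    for vals in seen[1:]:
        assert np.allclose(vals, reference)


def test_permutation_null_deterministic_and_positive_p(perm_setup):
    model, table = perm_setup
    nd1 = permutation_null(table, model, n_perm=49, seed=5)
    nd2 = permutation_null(table, model, n_perm=49, seed=5)
    assert np.array_equal(nd1.null, nd2.null)
    assert np.all(nd1.empirical_p > 0)
    # the strong true path must look extreme against its null
    k = nd1.labels.index("seed~e")
    assert nd1.empirical_p[k] == pytest.approx(1.0 / 50.0)
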