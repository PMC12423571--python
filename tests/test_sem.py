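import numpy as np
import pandas as pd
import pytest

from seedpath.model import parse_model
from seedpath.sem import (
    SemData,
    _delta_matrix,
    effects_decomposition,
    fit_baseline,
    fit_indices,
    fit_ml,
    implied_covariance,
    preprocess_variables,
    robust_adjust,
    standardized_solution,
)
from seedpath.synthetic import simulate_sem_table, theta_from_maps


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------
def test_preprocess_log_then_minmax():
    df = pd.DataFrame(
        {"seed": [1.0, np.e, np.e**2], "footprint": [0.0, 25.0, 50.0]}
    )
    data = preprocess_variables(df, log_vars=("seed",))
    assert np.allclose(data.raw[:, 0], [0.0, 0.5, 1.0])
    assert np.allclose(data.raw[:, 1], [0.0, 0.5, 1.0])


def test_preprocess_rejects_nonpositive_log_and_constant():
    with pytest.raises(ValueError, match="non-positive"):
        preprocess_variables(pd.DataFrame({"seed": [0.0, 1.0]}), log_vars=("seed",))
    with pytest.raises(ValueError, match="constant"):
        preprocess_variables(pd.DataFrame({"footprint": [3.0, 3.0]}), log_vars=())


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------
def test_implied_covariance_without_paths_is_psi():
    model = parse_model("a ~~ b", variables=["a", "b"])
    # free pairs sorted: (a,a), (a,b), (b,b)
    S = implied_covariance(model, np.array([2.0, 0.5, 3.0]))
    assert np.allclose(S, [[2.0, 0.5], [0.5, 3.0]])


@pytest.mark.parametrize(
    "text,paths,resid,check",
    [
        # single path: Var(y) = b^2 + psi, Cov(x, y) = b
        ("y ~ x", {("y", "x"): 0.7}, {"y": 0.5, "x": 1.0},
         lambda S: np.isclose(S[0, 0], 0.49 + 0.5) and np.isclose(S[0, 1], 0.7)),
        # chain: Cov(x, y) = b1 * b2
        ("y ~ m\nm ~ x", {("y", "m"): 0.4, ("m", "x"): -0.5},
         {"y": 1.0, "m": 1.0, "x": 1.0},
         lambda S: np.isclose(S[0, 2], 0.4 * -0.5)),
    ],
)
def test_implied_covariance_closed_forms(text, paths, resid, check):
    model = parse_model(text, variables=list(resid))
    theta = theta_from_maps(model, paths, resid)
    S = implied_covariance(model, theta)
    assert check(S)
    assert np.allclose(S, S.T)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------
def test_zero_discrepancy_fixed_point(chain_model, chain_theta):
    """Feeding S = Sigma(theta0) must recover theta0 with F_ML ~ 0."""
    Sigma0 = implied_covariance(chain_model, chain_theta)
    data = SemData(n=500, cov=Sigma0, means=np.zeros(3),
                   names=tuple(chain_model.variables))
    fit = fit_ml(data, chain_model)
    assert fit.converged
    assert fit.fml < 1e-6
    assert np.allclose(fit.theta, chain_theta, atol=1e-5)


def test_ml_matches_per_equation_least_squares(chain_model, chain_theta):
    """For recursive systems ML equals equation-by-equation OLS."""
    df = simulate_sem_table(chain_model, chain_theta, 5000, seed=42)
    data = SemData.from_dataframe(df)
    fit = fit_ml(data, chain_model)
    x = df.to_numpy()
    # OLS of y on (m, x) and of m on x
    Xy = np.column_stack([x[:, 1], x[:, 2]])
    beta_y = np.linalg.lstsq(Xy - Xy.mean(0), x[:, 0] - x[:, 0].mean(), rcond=None)[0]
    beta_m = np.linalg.lstsq(
        (x[:, 2] - x[:, 2].mean())[:, None], x[:, 1] - x[:, 1].mean(), rcond=None
    )[0]
    assert np.allclose(fit.theta[:2], beta_y, atol=1e-4)
    assert np.allclose(fit.theta[2], beta_m, atol=1e-4)


def test_saturated_model_has_zero_statistic(chain_model, chain_theta):
    df = simulate_sem_table(chain_model, chain_theta, 400, seed=7)
    fit = fit_ml(SemData.from_dataframe(df), chain_model)
    assert fit.df == 0
    assert fit.statistic == 0.0


def test_parameter_recovery_full_structure(downsizing_model, downsizing_theta):
    df = simulate_sem_table(downsizing_model, downsizing_theta, 5000, seed=5)
    fit = fit_ml(SemData.from_dataframe(df), downsizing_model)
    assert fit.converged
    assert np.all(np.abs(fit.theta - downsizing_theta) < 0.05)


def test_fit_invariant_to_variable_ordering(chain_theta):
    m1 = parse_model("y ~ m + x\nm ~ x", variables=["y", "m", "x"])
    df = simulate_sem_table(m1, chain_theta, 2000, seed=3)
    m2 = parse_model("y ~ m + x\nm ~ x", variables=["x", "y", "m"])
    f1 = fit_ml(SemData.from_dataframe(df, ["y", "m", "x"]), m1)
    f2 = fit_ml(SemData.from_dataframe(df, ["x", "y", "m"]), m2)
    # same free parameters, identified by label
    t1 = dict(zip(f1.labels, f1.theta))
    t2 = dict(zip(f2.labels, f2.theta))
    for lab in t1:
        assert np.isclose(t1[lab], t2[lab], atol=1e-6), lab


def test_nested_models_have_ordered_statistics(chain_model, chain_theta):
    df = simulate_sem_table(chain_model, chain_theta, 1000, seed=9)
    data = SemData.from_dataframe(df)
    full = fit_ml(data, chain_model)  # saturated
    reduced = fit_ml(data, chain_model.drop_path("y", "x"))
    assert reduced.statistic >= full.statistic


# ---------------------------------------------------------------------------
# robust corrections
# ---------------------------------------------------------------------------
def test_scaling_factor_near_one_under_normality():
    model = parse_model("y ~ m\nm ~ x", variables=["y", "m", "x"])
    theta = theta_from_maps(
        model, {("y", "m"): 0.4, ("m", "x"): -0.5}, {"y": 0.6, "m": 0.75, "x": 1.0}
    )
    df = simulate_sem_table(model, theta, 20000, seed=21)
    data = SemData.from_dataframe(df)
    fit = robust_adjust(fit_ml(data, model), data)
    assert abs(fit.scaling_factor - 1.0) < 0.1
    ratio = fit.se_robust / fit.se
    assert np.all(np.abs(ratio - 1.0) < 0.1)


def test_robust_ses_inflate_under_heavy_tails():
    rng = np.random.default_rng(4)
    n = 20000
    x = rng.standard_t(3, n)
    m = -0.5 * x + rng.standard_t(3, n)
    y = 0.4 * m + rng.standard_t(3, n)
    model = parse_model("y ~ m\nm ~ x", variables=["y", "m", "x"])
    data = SemData.from_dataframe(pd.DataFrame({"y": y, "m": m, "x": x}))
    fit = robust_adjust(fit_ml(data, model), data)
    # variance-parameter sandwich SEs must blow up under t3 fourth moments
    labels = np.array(fit.labels)
    var_idx = [i for i, l in enumerate(labels) if "~~" in l]
    assert np.all(fit.se_robust[var_idx] > 1.5 * fit.se[var_idx])
    assert fit.scaling_factor != pytest.approx(1.0, abs=1e-3)


def test_delta_matrix_matches_finite_differences(chain_model, chain_theta):
    delta = _delta_matrix(chain_model, chain_theta)
    eps = 1e-7
    from seedpath.sem import _vech

    fd = np.empty_like(delta)
    for k in range(chain_model.n_free):
        tp = chain_theta.copy()
        tm = chain_theta.copy()
        tp[k] += eps
        tm[k] -= eps
        fd[:, k] = (
            _vech(implied_covariance(chain_model, tp))
            - _vech(implied_covariance(chain_model, tm))
        ) / (2 * eps)
    assert np.max(np.abs(delta - fd)) < 1e-6


# ---------------------------------------------------------------------------
# indices, standardization, effects
# ---------------------------------------------------------------------------
def test_fit_indices_boundary_cases(chain_model, chain_theta):
    df = simulate_sem_table(chain_model, chain_theta, 800, seed=2)
    data = SemData.from_dataframe(df)
    fit = fit_ml(data, chain_model.drop_path("y", "x"))
    baseline = fit_baseline(data)
    idx = fit_indices(fit, baseline)
    assert 0.0 <= idx["cfi"] <= 1.0
    assert idx["rmsea"] >= 0.0
    # T <= df forces RMSEA = 0 and CFI = 1
    fit.statistic = float(fit.df)
    idx = fit_indices(fit, baseline)
    assert idx["rmsea"] == 0.0
    assert idx["cfi"] == 1.0


def test_fit_indices_require_wellformed_baseline(chain_model, chain_theta):
    df = simulate_sem_table(chain_model, chain_theta, 300, seed=2)
    data = SemData.from_dataframe(df)
    fit = fit_ml(data, chain_model)
    with pytest.raises(ValueError, match="baseline"):
        fit_indices(fit, fit)


def test_standardized_solution_scale_invariant(chain_model, chain_theta):
    df = simulate_sem_table(chain_model, chain_theta, 2000, seed=13)
    std1 = standardized_solution(fit_ml(SemData.from_dataframe(df), chain_model))
    df2 = df.copy()
    df2["x"] = df2["x"] * 10.0  # rescaling a variable
    std2 = standardized_solution(fit_ml(SemData.from_dataframe(df2), chain_model))
    assert np.allclose(
        std1["std_estimate"].to_numpy(), std2["std_estimate"].to_numpy(), atol=1e-6
    )


def test_effects_decomposition_chain(chain_model):
    theta = theta_from_maps(
        chain_model,
        {("y", "m"): 0.4, ("y", "x"): 0.0, ("m", "x"): -0.5},
        {"y": 1.0, "m": 1.0, "x": 1.0},
    )
    Sigma0 = implied_covariance(chain_model, theta)
    data = SemData(n=100, cov=Sigma0, means=np.zeros(3),
                   names=tuple(chain_model.variables))
    fit = fit_ml(data, chain_model)
    eff = effects_decomposition(fit, "x", "y")
    assert eff["indirect"] == pytest.approx(-0.2, abs=1e-4)
    assert eff["direct"] == pytest.approx(0.0, abs=1e-4)
    assert eff["total"] == pytest.approx(eff["direct"] + eff["indirect"])


def test_effects_identity_holds_for_all_pairs(downsizing_model, downsizing_theta):
    df = simulate_sem_table(downsizing_model, downsizing_theta, 1500, seed=8)
    fit = fit_ml(SemData.from_dataframe(df), downsizing_model)
    for src in downsizing_model.variables:
        for tgt in downsizing_model.variables:
            if src == tgt:
                continue
            eff = effects_decomposition(fit, src, tgt)
            assert eff["total"] == pytest.approx(
                eff["direct"] + eff["indirect"], abs=1e-12
            )
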