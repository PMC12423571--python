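"""Maximum-likelihood estimation of recursive observed-variable path models.

Estimation minimises the classical covariance-structure discrepancy

.. math::

    F_{ML}(\\theta) = \\ln|\\Sigma(\\theta)| + \\mathrm{tr}(S\\Sigma^{-1}(\\theta))
                      - \\ln|S| - p,

with the model-implied covariance
:math:`\\Sigma(\\theta) = (I-B)^{-1}\\Psi(I-B)^{-T}`.  The test statistic is
the Wishart form :math:`T=(n-1)F_{ML}` with :math:`df = p(p+1)/2 - q` where
``q`` counts free parameters.  Means are not modelled.

Robust ("MLR"-style) corrections use the empirical fourth-moment matrix of
the covariance elements: sandwich standard errors and a mean-scaled test
statistic :math:`T/c` with :math:`c = \\mathrm{tr}(U\\Gamma)/df` (under
multivariate normality :math:`c \\to 1`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import PathModel

__all__ = [
    "SemData",
    "SemFit",
    "preprocess_variables",
    "implied_covariance",
    "fit_ml",
    "fit_baseline",
    "robust_adjust",
    "fit_indices",
    "standardized_solution",
    "effects_decomposition",
]

DEFAULT_LOG_VARS = ("seed", "mass_extant", "mass_extinct")


# ---------------------------------------------------------------------------
# data container and preprocessing
# ---------------------------------------------------------------------------
@dataclass
class SemData:
    """Sample moments plus the raw matrix needed for robust corrections."""

    n: int
    cov: np.ndarray
    means: np.ndarray
    names: tuple[str, ...]
    raw: np.ndarray | None = None
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.names)
        if self.cov.shape != (p, p):
            raise ValueError("covariance shape does not match variable names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("sample covariance must be symmetric")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, names: list[str] | None = None) -> "SemData":
        if names is None:
            names = list(df.columns)
        x = df[names].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError("missing values in SEM data")
        return cls(
            n=x.shape[0],
            cov=np.cov(x, rowvar=False, ddof=1),
            means=x.mean(axis=0),
            names=tuple(names),
            raw=x,
        )


def preprocess_variables(
    table: pd.DataFrame,
    log_vars: tuple[str, ...] = DEFAULT_LOG_VARS,
    variables: list[str] | None = None,
) -> SemData:
    """Log-transform biological size variables, then min-max scale to [0, 1].

    Seed widths and body masses are natural-log transformed to tame the
    right skew of size distributions; every variable is then scaled to the
    unit interval so unstandardized coefficients are comparable across
    predictors.  The per-variable ``(min, max)`` constants (post-log) are
    stored on the returned :class:`SemData`.
    """
    if variables is None:
        variables = [c for c in table.columns]
    out = {}
    scaling: dict[str, tuple[float, float]] = {}
    for name in variables:
        vals = table[name].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing values in variable {name!r}")
        if name in log_vars:
            if np.any(vals <= 0):
                raise ValueError(f"non-positive value in log variable {name!r}")
            vals = np.log(vals)
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            raise ValueError(f"constant variable {name!r}")
        out[name] = (vals - lo) / (hi - lo)
        scaling[name] = (lo, hi)
    data = SemData.from_dataframe(pd.DataFrame(out), variables)
    data.scaling = scaling
    return data


# ---------------------------------------------------------------------------
# implied covariance and derivatives
# ---------------------------------------------------------------------------
def implied_covariance(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance Sigma = (I-B)^-1 Psi (I-B)^-T."""
    B, Psi = model.build_matrices(theta)
    p = model.n_vars
    A = np.linalg.solve(np.eye(p) - B, np.eye(p))
    return A @ Psi @ A.T


def _vech_indices(p: int) -> list[tuple[int, int]]:
    return [(i, j) for j in range(p) for i in range(j, p)]


def _vech(m: np.ndarray) -> np.ndarray:
    p = m.shape[0]
    return np.array([m[i, j] for i, j in _vech_indices(p)])


def _duplication(p: int) -> np.ndarray:
    """D with vec(M) = D vech(M) for symmetric M."""
    pairs = _vech_indices(p)
    D = np.zeros((p * p, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        D[j * p + i, k] = 1.0
        D[i * p + j, k] = 1.0
    return D


def _delta_matrix(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Jacobian d vech(Sigma) / d theta, analytically."""
    p = model.n_vars
    B, Psi = model.build_matrices(theta)
    A = np.linalg.solve(np.eye(p) - B, np.eye(p))
    Sigma = A @ Psi @ A.T
    cols = []
    idx = {v: k for k, v in enumerate(model.variables)}
    for t, s in model.regressions:
        E = np.zeros((p, p))
        E[idx[t], idx[s]] = 1.0
        G = A @ E @ Sigma
        cols.append(_vech(G + G.T))
    for i, j in model.free_psi_pairs():
        E = np.zeros((p, p))
        E[i, j] = 1.0
        E[j, i] = 1.0
        cols.append(_vech(A @ E @ A.T))
    return np.column_stack(cols)


def _fml_and_grad(model: PathModel, theta: np.ndarray, S: np.ndarray, logdet_S: float):
    p = model.n_vars
    B, Psi = model.build_matrices(theta)
    I = np.eye(p)
    try:
        A = np.linalg.solve(I - B, I)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)
    Sigma = A @ Psi @ A.T
    try:
        # Cholesky doubles as the PD check (slogdet's sign alone would pass
        # indefinite matrices with an even number of negative eigenvalues)
        C = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e12 + float(np.sum(theta**2)), 2.0 * theta
    logdet = 2.0 * float(np.sum(np.log(np.diag(C))))
    Sinv = np.linalg.solve(Sigma, I)
    f = logdet + float(np.trace(S @ Sinv)) - logdet_S - p
    # dF/dSigma = Sigma^-1 - Sigma^-1 S Sigma^-1
    W = Sinv - Sinv @ S @ Sinv
    idx = {v: k for k, v in enumerate(model.variables)}
    grad = np.empty(model.n_free)
    k = 0
    for t, s in model.regressions:
        E = np.zeros((p, p))
        E[idx[t], idx[s]] = 1.0
        G = A @ E @ Sigma
        grad[k] = float(np.sum(W * (G + G.T)))
        k += 1
    for i, j in model.free_psi_pairs():
        E = np.zeros((p, p))
        E[i, j] = 1.0
        E[j, i] = 1.0
        grad[k] = float(np.sum(W * (A @ E @ A.T)))
        k += 1
    return f, grad


def _ols_start(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Per-equation least squares on the sample covariance.

    For recursive systems whose only endogenous residual covariances are the
    explicitly freed pairs, this is at or near the ML solution and makes an
    excellent starting point in general.
    """
    idx = {v: k for k, v in enumerate(model.variables)}
    theta = np.zeros(model.n_free)
    resid_var = {v: S[idx[v], idx[v]] for v in model.variables}
    coef: dict[tuple[str, str], float] = {}
    for t in model.endogenous:
        ps = model.parents(t)
        pi = [idx[s] for s in ps]
        ti = idx[t]
        Sxx = S[np.ix_(pi, pi)]
        sxy = S[pi, ti]
        try:
            b = np.linalg.solve(Sxx, sxy)
        except np.linalg.LinAlgError:
            b = np.zeros(len(pi))
        for s, bs in zip(ps, b):
            coef[(t, s)] = float(bs)
        resid_var[t] = max(float(S[ti, ti] - sxy @ b), 1e-4 * S[ti, ti])
    for k, (t, s) in enumerate(model.regressions):
        theta[k] = coef.get((t, s), 0.0)
    exo = set(model.exogenous)
    for k, (i, j) in enumerate(model.free_psi_pairs(), start=len(model.regressions)):
        vi, vj = model.variables[i], model.variables[j]
        if i == j:
            theta[k] = resid_var[vi]
        elif vi in exo and vj in exo:
            theta[k] = S[i, j]
        else:
            theta[k] = 0.0
    return theta


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------
@dataclass
class SemFit:
    """Result of an ML path-model fit (optionally with robust corrections)."""

    model: PathModel
    data: SemData
    theta: np.ndarray
    se: np.ndarray
    fml: float
    statistic: float
    df: int
    converged: bool
    implied: np.ndarray
    se_robust: np.ndarray | None = None
    scaling_factor: float = 1.0
    baseline_statistic: float | None = None
    baseline_df: int | None = None

    @property
    def labels(self) -> list[str]:
        return self.model.parameter_labels()

    def _active_se(self, robust: bool | None = None) -> np.ndarray:
        if robust is None:
            robust = self.se_robust is not None
        if robust:
            if self.se_robust is None:
                raise ValueError("robust SEs not computed; call robust_adjust")
            return self.se_robust
        return self.se

    def z_values(self, robust: bool | None = None) -> np.ndarray:
        se = self._active_se(robust)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se > 0, self.theta / se, np.nan)

    def p_values(self, robust: bool | None = None) -> np.ndarray:
        z = self.z_values(robust)
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def statistic_scaled(self) -> float:
        return self.statistic / self.scaling_factor

    def parameter_table(self, robust: bool | None = None) -> pd.DataFrame:
        se = self._active_se(robust)
        return pd.DataFrame(
            {
                "label": self.labels,
                "estimate": self.theta,
                "se": se,
                "z": self.z_values(robust),
                "p": self.p_values(robust),
            }
        )

    def path_p_value(self, target: str, source: str, robust: bool | None = None) -> float:
        k = list(self.model.regressions).index((target, source))
        return float(self.p_values(robust)[k])


def _normal_theory_v(Sigma: np.ndarray) -> np.ndarray:
    p = Sigma.shape[0]
    D = _duplication(p)
    Sinv = np.linalg.inv(Sigma)
    return 0.5 * D.T @ np.kron(Sinv, Sinv) @ D


def fit_ml(
    data: SemData,
    model: PathModel,
    max_restarts: int = 5,
    gtol: float = 1e-7,
    rng: np.random.Generator | None = None,
) -> SemFit:
    """Fit a recursive path model by maximum likelihood.

    Starts from the per-equation least-squares solution; falls back to up
    to ``max_restarts`` jittered restarts if the quasi-Newton search fails
    to drive the gradient below ``gtol``.
    """
    if tuple(data.names) != tuple(model.variables):
        raise ValueError(
            f"data variables {data.names} do not match model {model.variables}"
        )
    p = model.n_vars
    if data.n <= p:
        raise ValueError("sample size must exceed the number of variables")
    S = data.cov
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular")

    df = p * (p + 1) // 2 - model.n_free
    if df < 0:
        raise ValueError("model has more free parameters than sample moments")

    rng = rng or np.random.default_rng(0)
    start = _ols_start(model, S)

    def fg(theta):
        return _fml_and_grad(model, theta, S, logdet_S)

    # scale-aware convergence: judge the gradient through per-parameter
    # natural scales so min-max-scaled data (tiny variances) are not
    # penalised by large raw gradient components
    idx = {v: k for k, v in enumerate(model.variables)}
    scales = np.empty(model.n_free)
    for k, (t, s) in enumerate(model.regressions):
        scales[k] = np.sqrt(S[idx[s], idx[s]] / S[idx[t], idx[t]])
    for k, (i, j) in enumerate(model.free_psi_pairs(), start=len(model.regressions)):
        scales[k] = np.sqrt(S[i, i] * S[j, j])

    def polish(x: np.ndarray) -> np.ndarray:
        # Newton refinement: L-BFGS-B's line search can stall while the raw
        # gradient is still large on min-max-scaled data
        for _ in range(20):
            f0, g = fg(x)
            if float(np.max(np.abs(g) * scales)) < max(gtol * 100, 1e-6):
                break
            H = np.empty((x.size, x.size))
            eps = 1e-6 * np.maximum(np.abs(x), scales)
            for k in range(x.size):
                xp = x.copy()
                xp[k] += eps[k]
                H[:, k] = (fg(xp)[1] - g) / eps[k]
            H = 0.5 * (H + H.T)
            w = np.linalg.eigvalsh(H)
            if w.min() < 1e-10:
                H = H + (1e-8 + abs(w.min())) * np.eye(x.size)
            step = np.linalg.solve(H, -g)
            t = 1.0
            for _ls in range(30):
                f1, _ = fg(x + t * step)
                if f1 < f0:
                    x = x + t * step
                    break
                t *= 0.5
            else:
                break
        return x

    best = None
    jitter_sd = 0.1 * float(np.sqrt(np.mean(np.diag(S))))
    for attempt in range(max_restarts + 1):
        x0 = start if attempt == 0 else start + rng.normal(0, jitter_sd, size=start.shape)
        res = optimize.minimize(
            fg,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-14},
        )
        x = polish(res.x)
        f, g = fg(x)
        res.x = x
        ok = float(np.max(np.abs(g) * scales)) < max(gtol * 100, 1e-5)
        if best is None or f < best[0]:
            best = (f, res.x, ok)
        if ok:
            break
    fml, theta, converged = best
    fml = max(fml, 0.0)
    Sigma = implied_covariance(model, theta)

    # normal-theory covariance of theta-hat: (Delta' V Delta)^-1 / (n-1)
    Delta = _delta_matrix(model, theta)
    V = _normal_theory_v(Sigma)
    H = Delta.T @ V @ Delta
    try:
        acov = np.linalg.inv(H) / (data.n - 1)
        se = np.sqrt(np.clip(np.diag(acov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(model.n_free, np.nan)
        converged = False

    statistic = (data.n - 1) * fml if df > 0 else 0.0
    if df == 0:
        fml = 0.0 if fml < 1e-8 else fml
    return SemFit(
        model=model,
        data=data,
        theta=theta,
        se=se,
        fml=fml,
        statistic=statistic,
        df=df,
        converged=bool(converged),
        implied=Sigma,
    )


def fit_baseline(data: SemData) -> SemFit:
    """Independence baseline: free variances, every covariance fixed at zero.

    Has the closed-form solution psi_ii = s_ii, so no optimisation is run.
    """
    p = len(data.names)
    model = PathModel(tuple(data.names), (), (), free_exogenous_block=False)
    S = data.cov
    theta = np.diag(S).copy()
    sign, logdet_S = np.linalg.slogdet(S)
    fml = float(np.sum(np.log(np.diag(S))) - logdet_S)
    df = p * (p + 1) // 2 - p
    se = np.sqrt(2.0 / (data.n - 1)) * np.diag(S)
    return SemFit(
        model=model,
        data=data,
        theta=theta,
        se=se,
        fml=max(fml, 0.0),
        statistic=(data.n - 1) * max(fml, 0.0),
        df=df,
        converged=True,
        implied=np.diag(np.diag(S)),
    )


def robust_adjust(fit: SemFit, data: SemData | None = None) -> SemFit:
    """Attach sandwich standard errors and a scaled test statistic.

    The asymptotic covariance of the sample covariances (``Gamma``) is
    estimated from the raw data's fourth moments; under multivariate
    normality the scaling factor ``c`` tends to 1 and the sandwich reduces
    to the normal-theory covariance.
    """
    data = data or fit.data
    if data.raw is None:
        raise ValueError("raw data required for robust corrections")
    x = data.raw
    n = x.shape[0]
    d = x - x.mean(axis=0)
    pairs = _vech_indices(x.shape[1])
    # moment deviations: d_i d_j - mean(d_i d_j)
    prods = np.column_stack([d[:, i] * d[:, j] for i, j in pairs])
    prods -= prods.mean(axis=0)
    Gamma = (prods.T @ prods) / n

    Delta = _delta_matrix(fit.model, fit.theta)
    V = _normal_theory_v(fit.implied)
    H = Delta.T @ V @ Delta
    Hinv = np.linalg.inv(H)
    meat = Delta.T @ V @ Gamma @ V @ Delta
    acov = Hinv @ meat @ Hinv / (n - 1)
    fit.se_robust = np.sqrt(np.clip(np.diag(acov), 0, None))

    if fit.df > 0:
        U = V - V @ Delta @ Hinv @ Delta.T @ V
        c = float(np.trace(U @ Gamma)) / fit.df
        fit.scaling_factor = c if c > 0 else 1.0
    else:
        fit.scaling_factor = 1.0  # undefined at df = 0
    return fit


def fit_indices(fit: SemFit, baseline: SemFit, robust: bool = False) -> dict:
    """Chi-square p, CFI and RMSEA from a fitted model and its baseline.

    When ``robust`` is true the mean-scaled statistic is used for the test
    and the indices.
    """
    if baseline.df <= fit.df:
        raise ValueError("malformed baseline: df_b must exceed df")
    T = fit.statistic_scaled if robust else fit.statistic
    Tb = baseline.statistic_scaled if robust else baseline.statistic
    df, dfb = fit.df, baseline.df
    n = fit.data.n
    excess = max(T - df, 0.0)
    denom = max(Tb - dfb, T - df, 0.0)
    cfi = 1.0 - (excess / denom if denom > 0 else 0.0)
    rmsea = float(np.sqrt(excess / (df * (n - 1)))) if df > 0 else 0.0
    chi2_p = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
    return {
        "statistic": float(T),
        "df": int(df),
        "chi2_p": chi2_p,
        "cfi": float(cfi),
        "rmsea": rmsea,
    }


def standardized_solution(fit: SemFit) -> pd.DataFrame:
    """Standardize estimates by the implied standard deviations.

    Path coefficients are multiplied by SD(source)/SD(target); free
    covariances are converted to correlations.
    """
    Sigma = fit.implied
    sd = np.sqrt(np.diag(Sigma))
    if np.any(sd <= 0):
        raise ValueError("zero implied variance; cannot standardize")
    idx = {v: k for k, v in enumerate(fit.model.variables)}
    std = np.empty_like(fit.theta)
    k = 0
    for t, s in fit.model.regressions:
        std[k] = fit.theta[k] * sd[idx[s]] / sd[idx[t]]
        k += 1
    for i, j in fit.model.free_psi_pairs():
        if i == j:
            std[k] = fit.theta[k] / (sd[i] * sd[i])
        else:
            std[k] = fit.theta[k] / (sd[i] * sd[j])
        k += 1
    return pd.DataFrame({"label": fit.labels, "std_estimate": std})


def effects_decomposition(fit: SemFit, source: str, target: str) -> dict:
    """Direct, indirect and total effect of ``source`` on ``target``.

    Total effects are :math:`(I-B)^{-1} - I`; the indirect effect is the
    total minus the direct path coefficient.
    """
    model = fit.model
    B, _ = model.build_matrices(fit.theta)
    p = model.n_vars
    total_m = np.linalg.solve(np.eye(p) - B, np.eye(p)) - np.eye(p)
    i, j = model.index(target), model.index(source)
    direct = float(B[i, j])
    total = float(total_m[i, j])
    return {"direct": direct, "indirect": total - direct, "total": total}
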