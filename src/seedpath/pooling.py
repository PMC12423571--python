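"""Rubin's-rules pooling across imputation replicates and backward pruning.

Parameter pooling follows Rubin's rules: the pooled estimate is the mean
across replicates, its total variance combines the mean within-imputation
variance with the (1 + 1/m)-inflated between-imputation variance, and
inference uses a t reference with the classical Rubin degrees of freedom.
Chi-square statistics are pooled with the D2 (statistic-pooling)
combination rule.  Model refinement removes the directed path with the
highest pooled p-value, refits, and repeats until all remaining paths are
significant; the permitted residual covariances are structural and never
pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import PathModel
from .sem import SemData, SemFit, fit_baseline, fit_indices, fit_ml, robust_adjust, standardized_solution

__all__ = [
    "PooledFit",
    "PruneTrace",
    "pool_rubin",
    "pool_fit_stat",
    "prune_stepwise",
    "evaluate_fit_criteria",
    "fit_replicates",
]

#: final-model gates: RMSEA strictly below 0.05, CFI strictly above 0.95,
#: chi-square test not significant
FIT_CRITERIA = {"rmsea_max": 0.05, "cfi_min": 0.95, "chi2_p_min": 0.05}


@dataclass
class PooledFit:
    """Rubin-pooled parameter table plus pooled fit statistic and indices."""

    labels: list[str]
    estimate: np.ndarray  # q-bar
    within: np.ndarray  # U-bar
    between: np.ndarray  # B_m
    total: np.ndarray  # T_m
    df: np.ndarray  # Rubin nu per parameter
    z: np.ndarray
    p: np.ndarray
    m: int
    statistic: float | None = None
    statistic_p: float | None = None
    indices: dict = field(default_factory=dict)
    std_estimate: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "estimate": self.estimate,
                "within_var": self.within,
                "between_var": self.between,
                "total_var": self.total,
                "df": self.df,
                "z": self.z,
                "p": self.p,
            }
        )

    def path_p(self, model: PathModel, target: str, source: str) -> float:
        k = list(model.regressions).index((target, source))
        return float(self.p[k])


def rubin_combine(estimates: np.ndarray, variances: np.ndarray) -> dict[str, np.ndarray]:
    """Rubin's rules on (m, k) arrays of estimates and squared SEs.

    Returns pooled estimate, within/between/total variances, Rubin degrees
    of freedom, and the t-referenced two-sided p-value.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    m = est.shape[0]
    if m < 2:
        raise ValueError("pooling requires >=2 replicates")
    qbar = est.mean(axis=0)
    ubar = var.mean(axis=0)
    bm = est.var(axis=0, ddof=1)
    tm = ubar + (1 + 1 / m) * bm
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * bm / ubar
        nu = np.where(bm > 0, (m - 1) * (1 + 1 / np.where(r > 0, r, np.inf)) ** 2, np.inf)
        z = qbar / np.sqrt(tm)
    p = np.where(
        np.isfinite(nu),
        2 * stats.t.sf(np.abs(z), np.where(np.isfinite(nu), nu, 1)),
        2 * stats.norm.sf(np.abs(z)),
    )
    return {
        "estimate": qbar, "within": ubar, "between": bm, "total": tm,
        "df": nu, "z": z, "p": p,
    }


def pool_rubin(fits: list[SemFit], robust: bool | None = None) -> PooledFit:
    """Combine m replicate fits of the same model by Rubin's rules."""
    m = len(fits)
    if m < 2:
        raise ValueError("pooling requires >=2 replicates")
    model = fits[0].model
    for f in fits[1:]:
        if f.model.regressions != model.regressions or f.model.variables != model.variables:
            raise ValueError("replicate fits use different models")
    if not all(f.converged for f in fits):
        raise ValueError("all replicate fits must have converged")
    est = np.stack([f.theta for f in fits])
    ses = np.stack([f._active_se(robust) for f in fits])
    c = rubin_combine(est, ses**2)
    std = np.stack([standardized_solution(f)["std_estimate"].to_numpy() for f in fits])
    return PooledFit(
        labels=fits[0].labels,
        estimate=c["estimate"],
        within=c["within"],
        between=c["between"],
        total=c["total"],
        df=c["df"],
        z=c["z"],
        p=c["p"],
        m=m,
        std_estimate=std.mean(axis=0),
    )


def pool_fit_stat(fits: list[SemFit], robust: bool | None = None) -> tuple[float, float]:
    """D2 pooling of the m chi-square statistics.

    Returns ``(D2, p)`` where ``D2`` is referred to an F distribution with
    ``(df, nu2)`` degrees of freedom.  With identical statistics across
    replicates the pooled p approaches the single-fit chi-square p.
    """
    m = len(fits)
    dfs = {f.df for f in fits}
    if len(dfs) != 1:
        raise ValueError("replicate fits have unequal df")
    k = dfs.pop()
    if k == 0:
        return 0.0, 1.0
    use_robust = robust if robust is not None else fits[0].se_robust is not None
    d = np.array([f.statistic_scaled if use_robust else f.statistic for f in fits])
    if m == 1:
        return float(d[0] / k), float(stats.chi2.sf(d[0], k))
    sq = np.sqrt(d)
    r2 = (1 + 1 / m) * sq.var(ddof=1)
    D2 = (d.mean() / k - (m + 1) / (m - 1) * r2) / (1 + r2)
    D2 = max(D2, 0.0)
    nu2 = k ** (-3 / m) * (m - 1) * (1 + 1 / r2) ** 2 if r2 > 0 else np.inf
    if np.isfinite(nu2):
        p = float(stats.f.sf(D2, k, nu2))
    else:
        p = float(stats.chi2.sf(D2 * k, k))
    return float(D2), p


def pooled_indices(fits: list[SemFit], baselines: list[SemFit], robust: bool | None = None) -> dict:
    """Pooled chi-square p plus CFI/RMSEA from the pooled statistics."""
    D2, p = pool_fit_stat(fits, robust)
    D2b, _ = pool_fit_stat(baselines, robust)
    df = fits[0].df
    dfb = baselines[0].df
    n = int(np.mean([f.data.n for f in fits]))
    T = D2 * df
    Tb = D2b * dfb
    excess = max(T - df, 0.0)
    denom = max(Tb - dfb, T - df, 0.0)
    cfi = 1.0 - (excess / denom if denom > 0 else 0.0)
    rmsea = float(np.sqrt(excess / (df * (n - 1)))) if df > 0 else 0.0
    return {"statistic": T, "df": df, "chi2_p": p, "cfi": cfi, "rmsea": rmsea}


def fit_replicates(
    datasets: list[SemData],
    model: PathModel,
    robust: bool = True,
) -> tuple[list[SemFit], list[SemFit]]:
    """Fit model and independence baseline on every replicate dataset."""
    fits, baselines = [], []
    for data in datasets:
        f = fit_ml(data, model)
        b = fit_baseline(data)
        if robust:
            f = robust_adjust(f, data)
            b = robust_adjust(b, data)
        fits.append(f)
        baselines.append(b)
    return fits, baselines


@dataclass
class PruneTrace:
    """Record of the backward path-removal sequence and the final model."""

    steps: list[dict]
    final_model: PathModel
    final_pooled: PooledFit
    criteria: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def evaluate_fit_criteria(indices: dict) -> dict:
    """Strict gates: RMSEA < 0.05, CFI > 0.95, chi-square p > 0.05."""
    report = {
        "rmsea_ok": bool(indices["rmsea"] < FIT_CRITERIA["rmsea_max"]),
        "cfi_ok": bool(indices["cfi"] > FIT_CRITERIA["cfi_min"]),
        "chi2_ok": bool(indices["chi2_p"] > FIT_CRITERIA["chi2_p_min"]),
    }
    report["all_ok"] = all(report.values())
    return report


def _pooled_for(datasets: list[SemData], model: PathModel, robust: bool) -> PooledFit:
    fits, baselines = fit_replicates(datasets, model, robust)
    pooled = pool_rubin(fits)
    idx = pooled_indices(fits, baselines)
    pooled.statistic = idx["statistic"]
    pooled.statistic_p = idx["chi2_p"]
    pooled.indices = idx
    return pooled


def prune_stepwise(
    datasets: list[SemData],
    model: PathModel,
    alpha: float = 0.05,
    robust: bool = True,
    protected: tuple[tuple[str, str], ...] = (),
) -> PruneTrace:
    """Backward removal of non-significant directed paths.

    At each step the directed path with the highest pooled p-value is
    removed if that p exceeds ``alpha`` (ties broken toward the smaller
    mean |standardized estimate|); residual covariances are structural and
    kept.  Stops when every remaining path is significant or no directed
    path remains.
    """
    steps: list[dict] = []
    current = model
    pooled = _pooled_for(datasets, current, robust)
    while True:
        eligible = [e for e in current.regressions if e not in protected]
        if not eligible:
            break
        ps = np.array([pooled.path_p(current, t, s) for t, s in eligible])
        worst = ps.max()
        if worst <= alpha:
            break
        tied = [i for i, v in enumerate(ps) if np.isclose(v, worst)]
        if len(tied) > 1 and pooled.std_estimate is not None:
            regs = list(current.regressions)
            stds = [abs(pooled.std_estimate[regs.index(eligible[i])]) for i in tied]
            drop_i = tied[int(np.argmin(stds))]
        else:
            drop_i = int(np.argmax(ps))
        t, s = eligible[drop_i]
        current = current.drop_path(t, s)
        pooled = _pooled_for(datasets, current, robust)
        steps.append(
            {
                "removed": f"{t}~{s}",
                "pooled_p": float(worst),
                "rmsea": pooled.indices["rmsea"],
                "cfi": pooled.indices["cfi"],
                "chi2_p": pooled.indices["chi2_p"],
            }
        )
    return PruneTrace(
        steps=steps,
        final_model=current,
        final_pooled=pooled,
        criteria=evaluate_fit_criteria(pooled.indices),
    )
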